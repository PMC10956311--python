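"""Synthetic tissue label maps and cohorts with known ground truth.

Real whole-slide images and the patient records behind PDX engraftment
cohorts are not publicly deposited, so every downstream stage of the
pipeline is exercised on synthetic stand-ins generated here:

* :func:`generate_label_map` emits a 2-D grid of tissue-class patches
  (adipose, background, necrosis, carcinoma, stroma, TDLU) with a single
  dominant carcinoma mass and controllable intratumoral composition, plus an
  aligned per-patch lymphocyte area fraction.
* :func:`generate_cohort` draws clinicopathological covariates with
  marginals mimicking a primary breast cancer PDX cohort and a binary
  engraftment outcome from a known logistic model, keeping the true
  coefficient vector alongside for parameter-recovery tests.
* :func:`expand_counts` turns printed outcome-by-category contingency
  counts into record-level data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage


class TissueClass(IntEnum):
    """Patch-level tissue classes of the morphometric taxonomy."""

    ADIPOSE = 1
    BACKGROUND = 2
    NECROSIS = 3
    CARCINOMA = 4
    STROMA = 5
    TDLU = 6


#: Intratumoral composition used when a map spec gives none; loosely follows
#: the engraftment-failure group means of a primary breast cancer cohort
#: (proportions of the six patch classes inside the tumour boundary).
DEFAULT_COMPOSITION: dict[TissueClass, float] = {
    TissueClass.ADIPOSE: 0.064,
    TissueClass.BACKGROUND: 0.030,
    TissueClass.NECROSIS: 0.074,
    TissueClass.CARCINOMA: 0.444,
    TissueClass.STROMA: 0.338,
    TissueClass.TDLU: 0.050,
}


class SynthSpecError(ValueError):
    """A synthetic-data spec violates its invariants."""


@dataclass
class TissueLabelMap:
    """A per-patch tissue-class grid plus an aligned lymphocyte area mask.

    Parameters
    ----------
    labels
        2-D integer array of :class:`TissueClass` codes (1..6).
    lymph_fraction
        2-D float array, same shape; each cell is the fraction of that
        patch's area occupied by lymphocytes, in [0, 1].  Zero wherever the
        patch is background.
    patch_px
        Side length of one patch in pixels (112 px at 400x magnification by
        convention).
    tumor_mask
        Optional ground-truth boolean mask of the generated tumour mass;
        populated by :func:`generate_label_map`, ignored by readers.
    """

    labels: np.ndarray
    lymph_fraction: np.ndarray
    patch_px: int = 112
    tumor_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.lymph_fraction = np.asarray(self.lymph_fraction, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise SynthSpecError("labels must be a nonempty 2-D grid")
        if self.labels.shape != self.lymph_fraction.shape:
            raise SynthSpecError(
                "labels and lymph_fraction shapes differ: "
                f"{self.labels.shape} vs {self.lymph_fraction.shape}"
            )
        codes = {int(c) for c in TissueClass}
        present = set(np.unique(self.labels).tolist())
        if not present <= codes:
            raise SynthSpecError(f"unknown tissue codes: {sorted(present - codes)}")
        lf = self.lymph_fraction
        if np.any(~np.isfinite(lf)) or lf.min() < 0.0 or lf.max() > 1.0:
            raise SynthSpecError("lymph_fraction values must lie in [0, 1]")
        if np.any(lf[self.labels == TissueClass.BACKGROUND] != 0.0):
            raise SynthSpecError("lymph_fraction must be 0 on background patches")
        if self.patch_px < 1:
            raise SynthSpecError("patch_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class SynthMapSpec:
    """Recipe for one synthetic label map.

    ``target_composition`` gives the intended intratumoral mix of the six
    patch classes (fractions summing to 1); ``tumor_mass`` is the fraction
    of the whole grid covered by the single carcinoma mass; ``smoothness``
    is the Gaussian kernel width (in patches) of the spatial random fields,
    so larger values give larger coherent tissue pockets.
    """

    shape: tuple[int, int] = (200, 200)
    target_composition: Mapping[TissueClass, float] | None = None
    tumor_mass: float = 0.30
    smoothness: float = 2.0
    mean_lymph_fraction: float = 0.02
    patch_px: int = 112
    seed: int = 0

    def composition(self) -> dict[TissueClass, float]:
        comp = dict(DEFAULT_COMPOSITION if self.target_composition is None
                    else {TissueClass(k): float(v)
                          for k, v in self.target_composition.items()})
        for cls in TissueClass:
            comp.setdefault(cls, 0.0)
        return comp

    def validate(self) -> None:
        rows, cols = self.shape
        if rows < 1 or cols < 1:
            raise SynthSpecError("shape must be positive")
        comp = self.composition()
        if any(v < 0 for v in comp.values()):
            raise SynthSpecError("composition fractions must be nonnegative")
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-9:
            raise SynthSpecError(f"composition must sum to 1, got {total!r}")
        if not 0.0 < self.tumor_mass <= 1.0:
            raise SynthSpecError("tumor_mass must lie in (0, 1]")
        if round(self.tumor_mass * rows * cols) < 1:
            raise SynthSpecError(
                f"grid {self.shape} too small to host tumor_mass={self.tumor_mass}"
            )
        if self.smoothness <= 0:
            raise SynthSpecError("smoothness must be positive")
        if not 0.0 <= self.mean_lymph_fraction <= 1.0:
            raise SynthSpecError("mean_lymph_fraction must lie in [0, 1]")


def _smooth_fields(rng: np.random.Generator, shape: tuple[int, int],
                   n: int, sigma: float) -> np.ndarray:
    """n independent unit-variance Gaussian random fields, smoothed."""
    fields = rng.standard_normal((n, *shape))
    for i in range(n):
        fields[i] = ndimage.gaussian_filter(fields[i], sigma=sigma, mode="wrap")
    sd = fields.std(axis=(1, 2), keepdims=True)
    sd[sd == 0] = 1.0
    return fields / sd


def _argmax_with_quota(fields: np.ndarray, mask: np.ndarray,
                       fractions: np.ndarray, n_iter: int = 120,
                       lr: float = 0.6) -> np.ndarray:
    """Assign each cell in ``mask`` the argmax class of offset fields.

    Offsets are calibrated iteratively so the realised class fractions
    inside the mask approach ``fractions``.  Classes with zero target get a
    -inf offset and never appear.
    """
    k = fields.shape[0]
    offsets = np.zeros(k)
    dead = fractions <= 0.0
    offsets[dead] = -np.inf
    sub = fields[:, mask]
    n_cells = sub.shape[1]
    assign = np.argmax(sub + offsets[:, None], axis=0)
    for _ in range(n_iter):
        realized = np.bincount(assign, minlength=k) / n_cells
        step = lr * (fractions - realized)
        step[dead] = 0.0
        offsets = offsets + step
        assign = np.argmax(sub + offsets[:, None], axis=0)
    return assign


def _tumor_mass_mask(rng: np.random.Generator, shape: tuple[int, int],
                     tumor_mass: float) -> np.ndarray:
    """A single simply connected star-shaped blob covering ~tumor_mass."""
    rows, cols = shape
    target_area = tumor_mass * rows * cols
    cy = rows / 2.0 + rng.uniform(-0.05, 0.05) * rows
    cx = cols / 2.0 + rng.uniform(-0.05, 0.05) * cols
    # smooth periodic radial perturbation keeps the blob star-shaped, hence
    # simply connected even after rasterisation
    n_harm = 4
    amp = rng.standard_normal(n_harm)
    phase = rng.uniform(0, 2 * np.pi, n_harm)
    yy, xx = np.mgrid[0:rows, 0:cols]
    theta = np.arctan2(yy - cy, xx - cx)
    wobble = np.zeros_like(theta)
    for h in range(n_harm):
        wobble += amp[h] * np.cos((h + 2) * theta + phase[h])
    peak = max(np.abs(wobble).max(), 1e-12)
    wobble *= 0.22 / peak
    dist = np.hypot(yy - cy, xx - cx)
    r0 = math.sqrt(target_area / math.pi)
    mask = dist <= r0 * (1.0 + wobble)
    # one corrective rescale toward the requested area (clipping at the grid
    # border can otherwise shrink the realised mass)
    realized = mask.sum()
    if realized > 0:
        r0 *= math.sqrt(target_area / realized)
        mask = dist <= r0 * (1.0 + wobble)
    if not mask.any():  # tiny grids: guarantee at least one tumour cell
        mask[int(min(cy, rows - 1)), int(min(cx, cols - 1))] = True
    return mask


def generate_label_map(spec: SynthMapSpec) -> TissueLabelMap:
    """Generate one synthetic tissue label map.

    The map carries a single simply connected carcinoma mass covering about
    ``spec.tumor_mass`` of the grid.  Cells inside the mass are assigned by
    per-class smoothed Gaussian random fields whose offsets are calibrated
    to hit ``spec.target_composition`` (the intratumoral mix).  Cells
    outside the mass draw from the non-carcinoma part of the composition,
    renormalised; if the composition is pure carcinoma the mass fills the
    whole grid.  The lymphocyte area fraction per patch is Beta-distributed
    around ``mean_lymph_fraction``, elevated inside stroma (mimicking
    stromal TILs) and zero on background.

    Identical spec (including seed) gives a bit-identical map.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    comp = spec.composition()
    classes = list(TissueClass)
    fractions = np.array([comp[c] for c in classes])
    carc_idx = classes.index(TissueClass.CARCINOMA)

    non_carc = fractions.copy()
    non_carc[carc_idx] = 0.0
    if non_carc.sum() <= 0.0:
        # degenerate pure-carcinoma composition: tumour is the whole grid
        mask = np.ones(spec.shape, dtype=bool)
    else:
        mask = _tumor_mass_mask(rng, spec.shape, spec.tumor_mass)

    labels = np.empty(spec.shape, dtype=np.uint8)
    fields = _smooth_fields(rng, spec.shape, len(classes), spec.smoothness)

    inside = _argmax_with_quota(fields, mask, fractions)
    labels[mask] = np.array([int(classes[i]) for i in range(len(classes))],
                            dtype=np.uint8)[inside]

    outside = ~mask
    if outside.any():
        ext = non_carc / non_carc.sum()
        ext_fields = _smooth_fields(rng, spec.shape, len(classes), spec.smoothness)
        assign = _argmax_with_quota(ext_fields, outside, ext)
        labels[outside] = np.array([int(c) for c in classes],
                                   dtype=np.uint8)[assign]

    lymph = _lymph_raster(rng, labels, spec.mean_lymph_fraction)
    return TissueLabelMap(labels=labels, lymph_fraction=lymph,
                          patch_px=spec.patch_px, tumor_mask=mask)


def _lymph_raster(rng: np.random.Generator, labels: np.ndarray,
                  mean_frac: float) -> np.ndarray:
    if mean_frac <= 0.0:
        return np.zeros(labels.shape)
    if mean_frac >= 1.0:
        out = np.ones(labels.shape)
    else:
        conc = 10.0
        out = rng.beta(mean_frac * conc, (1.0 - mean_frac) * conc,
                       size=labels.shape)
        out = np.clip(np.where(labels == TissueClass.STROMA, 1.5 * out, out),
                      0.0, 1.0)
    out[labels == TissueClass.BACKGROUND] = 0.0
    return out


# ---------------------------------------------------------------------------
# cohorts


def _default_covariate_params() -> dict:
    """Marginals mimicking a 353-patient primary breast cancer PDX cohort."""
    return {
        "age": {"mean": 50.9, "sd": 12.2, "lo": 18.0, "hi": 95.0},
        "ki67": {"mean": 39.0, "sd": 29.1},
        "size_cm": {"mean": 3.3, "sd": 2.2, "lo": 0.1, "hi": 20.0},
        "n_pos_ln": {"mean": 2.7, "sd": 8.5},
        "til_pct": {"mean": 11.0, "sd": 17.9},
        "subtype": {"HER2+": 21 / 353, "HR+": 152 / 353,
                    "HR+/HER2+": 33 / 353, "TNBC": 147 / 353},
        "nac": {"yes": 156 / 353, "no": 197 / 353},
        "hg": {"2": 158 / 353, "3": 195 / 353},
        "lvi": {"not identified": 200 / 353, "present": 153 / 353},
        "diagnosis": {"IDC": 315 / 353, "Other": 38 / 353},
        "miller_payne": {"1": 45 / 156, "2": 49 / 156, "3": 57 / 156,
                         "4": 5 / 156, "5": 0.0},
        "rcb_score": {"mean": 3.1, "sd": 1.0, "lo": 0.0, "hi": 5.5},
        # Dirichlet mean (x10000) over AP, BP, NP, carcinomaP, SP, TDLUP and
        # its concentration; carcinomaP absorbs the remainder
        "proportions": {"mean": {"AP": 620.0, "BP": 250.0, "NP": 720.0,
                                 "carcinomaP": 4640.0, "SP": 3280.0,
                                 "TDLUP": 490.0},
                        "concentration": 30.0},
        "tilp": {"shape": 1.2, "scale": 15.0},
    }


def default_true_beta() -> dict[str, float]:
    """Logistic outcome model used by default (config default, not dogma).

    Keys are either ``"intercept"``, a numeric column name, or
    ``"column:level"`` for a categorical indicator.  Effect sizes are
    loosely matched to multivariate odds ratios reported for PDX
    engraftment cohorts; the intercept sets prevalence near 0.17.
    """
    return {
        "intercept": -6.8,
        "age": math.log(0.96),
        "ki67": math.log(1.05),
        "nac:yes": math.log(3.27),
        "size_cm": math.log(1.20),
        "hg:3": math.log(4.34),
        "NP": math.log(1.927) / 1000.0,
        "ICP": math.log(1.820) / 1000.0,
    }


@dataclass
class CohortGenSpec:
    """Recipe for one synthetic cohort.

    ``beta`` is the true logistic outcome model (see
    :func:`default_true_beta` for the key syntax); ``invasive_fraction_dist``
    holds the Beta(a, b) parameters of the pathologist-assessed invasive
    carcinoma fraction.
    """

    n: int = 353
    covariate_params: dict = field(default_factory=_default_covariate_params)
    beta: dict[str, float] = field(default_factory=default_true_beta)
    invasive_fraction_dist: tuple[float, float] = (8.0, 2.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise SynthSpecError("cohort size n must be >= 1")
        for name, params in self.covariate_params.items():
            if isinstance(params, dict) and "sd" in params and params["sd"] <= 0:
                raise SynthSpecError(f"sd for {name!r} must be > 0")
        if any(not np.isfinite(v) for v in self.beta.values()):
            raise SynthSpecError("beta coefficients must be finite")
        a, b = self.invasive_fraction_dist
        if a <= 0 or b <= 0:
            raise SynthSpecError("Beta parameters must be > 0")


@dataclass
class SyntheticCohort:
    """A generated cohort table plus its ground-truth outcome model."""

    table: pd.DataFrame
    beta: dict[str, float]
    spec: CohortGenSpec


def _trunc_normal(rng: np.random.Generator, n: int, mean: float, sd: float,
                  lo: float = -np.inf, hi: float = np.inf) -> np.ndarray:
    """Normal draws with resampling outside [lo, hi] (clip as last resort)."""
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=bad.sum())
    return np.clip(out, lo, hi)


def _categorical(rng: np.random.Generator, n: int,
                 probs: Mapping[str, float]) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(levels, dtype=object), size=n, p=p)


def linear_predictor(frame: pd.DataFrame, beta: Mapping[str, float]) -> np.ndarray:
    """Evaluate a ``beta`` specification (see :func:`default_true_beta`)."""
    lp = np.zeros(len(frame))
    for key, coef in beta.items():
        if key == "intercept":
            lp += coef
        elif ":" in key:
            col, level = key.split(":", 1)
            lp += coef * (frame[col].astype(str) == level).to_numpy(float)
        else:
            lp += coef * frame[key].to_numpy(float)
    return lp


def generate_cohort(spec: CohortGenSpec) -> SyntheticCohort:
    """Draw a cohort with known covariate marginals and outcome model.

    Continuous covariates come from truncated normals; Ki-67 and stromal
    TIL percentages are floor-discretised to the 10-step grid used in
    routine pathology reporting; morphometric proportions are Dirichlet on
    the x10,000 scale so the six patch classes sum to exactly 10,000.  The
    binary outcome is Bernoulli(logistic(beta.x)) and the true beta is
    returned alongside the table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = spec.covariate_params
    n = spec.n

    frame = pd.DataFrame({"case_id": [f"case_{i:04d}" for i in range(n)]})
    a = p["age"]
    frame["age"] = _trunc_normal(rng, n, a["mean"], a["sd"], a["lo"], a["hi"])
    ki = _trunc_normal(rng, n, p["ki67"]["mean"], p["ki67"]["sd"], 0.0, 99.99)
    frame["ki67"] = (np.floor(ki / 10.0) * 10).astype(int)
    s = p["size_cm"]
    frame["size_cm"] = _trunc_normal(rng, n, s["mean"], s["sd"], s["lo"], s["hi"])
    frame["n_pos_ln"] = np.round(
        _trunc_normal(rng, n, p["n_pos_ln"]["mean"], p["n_pos_ln"]["sd"], 0.0)
    ).astype(int)
    til = _trunc_normal(rng, n, p["til_pct"]["mean"], p["til_pct"]["sd"], 0.0, 99.99)
    frame["til_pct"] = (np.floor(til / 10.0) * 10).astype(int)
    for cat in ("subtype", "nac", "hg", "lvi", "diagnosis"):
        frame[cat] = _categorical(rng, n, p[cat])

    nac_mask = frame["nac"].to_numpy() == "yes"
    mp = _categorical(rng, n, p["miller_payne"])
    frame["miller_payne"] = np.where(nac_mask, mp, None)
    r = p["rcb_score"]
    rcb = _trunc_normal(rng, n, r["mean"], r["sd"], r["lo"], r["hi"])
    frame["rcb_score"] = np.where(nac_mask, np.round(rcb, 2), np.nan)
    frame["rcb_class"] = np.where(
        nac_mask, np.select([rcb < 1.4, rcb < 3.3], ["I", "II"], "III"), None
    )

    af, bf = spec.invasive_fraction_dist
    frame["invasive_fraction"] = rng.beta(af, bf, size=n)

    prop = p["proportions"]
    order = ["AP", "BP", "NP", "carcinomaP", "SP", "TDLUP"]
    alpha = np.array([prop["mean"][k] for k in order]) / 10000.0
    alpha = alpha * prop["concentration"]
    draws = rng.dirichlet(alpha, size=n) * 10000.0
    for j, name in enumerate(order):
        frame[name] = draws[:, j]
    frame["ICP"] = frame["carcinomaP"] * frame["invasive_fraction"]
    tilp = rng.gamma(p["tilp"]["shape"], p["tilp"]["scale"], size=n)
    frame["TILP"] = np.clip(tilp, 0.0, 10000.0)

    lp = linear_predictor(frame, spec.beta)
    frame["engrafted"] = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
    return SyntheticCohort(table=frame, beta=dict(spec.beta), spec=spec)


# ---------------------------------------------------------------------------
# printed-count expansion


def expand_counts(counts: Mapping[str, tuple[int, int]],
                  variable: str = "category",
                  outcome: str = "engrafted") -> pd.DataFrame:
    """Expand outcome-by-category counts into one record per counted unit.

    ``counts`` maps each category to ``(n_failure, n_success)``.  The result
    has ``sum(n_failure + n_success)`` rows with columns ``variable`` and
    ``outcome`` (0 = failure, 1 = success), in category order, failures
    first — re-tabulating reproduces the input exactly.
    """
    cats: list[str] = []
    outs: list[int] = []
    for cat, (n_fail, n_succ) in counts.items():
        for name, count in ((cat, n_fail), (cat, n_succ)):
            if int(count) != count or count < 0:
                raise ValueError(
                    f"counts must be nonnegative integers, got {count!r} for {cat!r}"
                )
        cats.extend([cat] * (int(n_fail) + int(n_succ)))
        outs.extend([0] * int(n_fail) + [1] * int(n_succ))
    return pd.DataFrame({variable: pd.Series(cats, dtype=object),
                         outcome: pd.Series(outs, dtype=int)})
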