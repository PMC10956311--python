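"""Tumor boundary delineation and intratumoral morphometric proportions.

Given a per-patch tissue-class grid, the largest carcinoma mass is
delineated by morphological closing, hole filling and connected-component
selection; the six patch-class proportions inside that boundary are then
reported on the x10,000 scale, with the carcinoma proportion corrected by a
pathologist-assessed invasive fraction (ICP) and the lymphocyte area ratio
reported as TILP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology

from pdxms.synthdata import TissueClass, TissueLabelMap

SCALE = 10000.0


class NoTumorError(ValueError):
    """Raised when a label map contains no carcinoma patch."""


@dataclass
class TumorRegion:
    """A delineated tumour: filled single connected component of patches."""

    mask: np.ndarray
    n_patches: int
    boundary: list[tuple[int, int]]

    def validate(self) -> None:
        if self.n_patches < 1 or int(self.mask.sum()) != self.n_patches:
            raise ValueError("region mask inconsistent with n_patches")


@dataclass
class MorphometricProfile:
    """The intratumoral proportions, each on the x10,000 scale.

    AP adipose, BP background, NP necrosis, TDLUP terminal ductal lobular
    units, SP stroma; carcinomaP is the raw carcinoma patch proportion and
    ICP = carcinomaP x invasive_fraction its invasive-corrected version;
    TILP is the intratumoral lymphocyte area ratio.
    """

    AP: float
    BP: float
    NP: float
    TDLUP: float
    SP: float
    carcinomaP: float
    ICP: float
    TILP: float
    invasive_fraction: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("AP", "BP", "NP", "TDLUP", "SP", "carcinomaP", "ICP",
                 "TILP", "invasive_fraction")}


def _largest_component(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    structure = ndimage.generate_binary_structure(2, connectivity)
    lab, n = ndimage.label(mask, structure=structure)
    if n == 0:
        raise NoTumorError("no carcinoma component found")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        # tie: keep the component whose top-left-most cell is smallest in
        # (row, col) order
        def key(idx: int) -> tuple[int, int]:
            rr, cc = np.nonzero(lab == idx)
            order = np.lexsort((cc, rr))[0]
            return int(rr[order]), int(cc[order])

        best = [min(best, key=key)]
    return lab == best[0]


def _rim(mask: np.ndarray, connectivity: int = 2) -> list[tuple[int, int]]:
    structure = ndimage.generate_binary_structure(2, connectivity)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    rr, cc = np.nonzero(mask & ~interior)
    return [(int(r), int(c)) for r, c in zip(rr, cc)]


def delineate_tumor(label_map: TissueLabelMap, close_radius: int = 2,
                    connectivity: int = 2) -> TumorRegion:
    """Delineate the largest carcinoma mass on a label map.

    The binary carcinoma mask is morphologically closed with a square
    structuring element of the given radius (side ``2*close_radius + 1``),
    holes are filled, and the largest 8-connected component is returned
    (4-connectivity via ``connectivity=1``).  Ties on component size break
    to the component whose top-left-most cell is smallest in (row, col).

    Raises
    ------
    NoTumorError
        If the map contains no carcinoma patch.
    """
    carcinoma = np.asarray(label_map.labels) == TissueClass.CARCINOMA
    if not carcinoma.any():
        raise NoTumorError("label map contains no carcinoma patch")
    closed = carcinoma
    if close_radius > 0:
        footprint = morphology.footprint_rectangle(
            (2 * close_radius + 1, 2 * close_radius + 1))
        closed = morphology.closing(carcinoma, footprint=footprint)
        # closing must never lose the original carcinoma cells
        closed |= carcinoma
    filled = ndimage.binary_fill_holes(closed)
    mask = _largest_component(filled, connectivity=connectivity)
    mask = ndimage.binary_fill_holes(mask)
    return TumorRegion(mask=mask, n_patches=int(mask.sum()),
                       boundary=_rim(mask, connectivity=connectivity))


def compute_tilp(label_map: TissueLabelMap, region: TumorRegion) -> float:
    """Intratumoral lymphocyte area ratio, x10,000.

    Lymphocyte area summed over in-region patches divided by the total
    in-region patch area; with uniform patch size this is just the mean
    in-region lymphocyte fraction.
    """
    region.validate()
    return float(SCALE * label_map.lymph_fraction[region.mask].mean())


def compute_proportions(label_map: TissueLabelMap, region: TumorRegion,
                        invasive_fraction: float,
                        include_background: bool = True) -> MorphometricProfile:
    """Patch-class proportions inside the tumour boundary, x10,000.

    Each class proportion is ``10000 * n_class / n_patches`` with the
    denominator counting every patch inside the perimeter (background
    included by default; ``include_background=False`` switches to a
    tissue-only denominator).  ``ICP = carcinomaP * invasive_fraction``.
    """
    if not 0.0 <= invasive_fraction <= 1.0:
        raise ValueError("invasive_fraction must lie in [0, 1]")
    if region.mask.shape != label_map.shape:
        raise ValueError("region mask shape does not match map shape")
    region.validate()
    inside = np.asarray(label_map.labels)[region.mask]
    denom = inside.size
    if not include_background:
        denom = int((inside != TissueClass.BACKGROUND).sum())
        if denom == 0:
            raise ValueError("region contains only background patches")
    counts = {cls: int((inside == cls).sum()) for cls in TissueClass}
    prop = {cls: SCALE * counts[cls] / denom for cls in TissueClass}
    carcinoma_p = prop[TissueClass.CARCINOMA]
    return MorphometricProfile(
        AP=prop[TissueClass.ADIPOSE],
        BP=prop[TissueClass.BACKGROUND] if include_background else 0.0,
        NP=prop[TissueClass.NECROSIS],
        TDLUP=prop[TissueClass.TDLU],
        SP=prop[TissueClass.STROMA],
        carcinomaP=carcinoma_p,
        ICP=carcinoma_p * invasive_fraction,
        TILP=compute_tilp(label_map, region),
        invasive_fraction=invasive_fraction,
    )


def profile_case(label_map: TissueLabelMap, invasive_fraction: float,
                 close_radius: int = 2,
                 include_background: bool = True) -> MorphometricProfile:
    """Delineate and profile a single case in one call."""
    region = delineate_tumor(label_map, close_radius=close_radius)
    return compute_proportions(label_map, region, invasive_fraction,
                               include_background=include_background)


def profile_cohort(cases: dict[str, tuple[TissueLabelMap, float]],
                   close_radius: int = 2,
                   include_background: bool = True
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Profile many cases; returns (feature table, excluded case ids).

    ``cases`` maps case id to ``(label_map, invasive_fraction)``.  Cases
    without any carcinoma patch are excluded (and returned in the exclusion
    list) rather than failing the whole batch, mirroring slide-level
    exclusions in practice.
    """
    ids = list(cases)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids")
    rows, excluded = [], []
    for case_id, (label_map, frac) in cases.items():
        try:
            profile = profile_case(label_map, frac, close_radius=close_radius,
                                   include_background=include_background)
        except NoTumorError:
            excluded.append(case_id)
            continue
        rows.append({"case_id": case_id, **profile.as_dict()})
    if excluded:
        warnings.warn(f"excluded {len(excluded)} case(s) with no tumour: "
                      f"{excluded}", stacklevel=2)
    return pd.DataFrame(rows), excluded
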