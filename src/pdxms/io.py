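"""File formats and run configuration.

Cohort tables travel as CSV with a documented column dictionary; label maps
as single-channel 8-bit indexed PNG (tissue codes 1-6) with a 16-bit PNG
sidecar for the lymphocyte area fraction (value/65535) and a small YAML
header carrying patch size, seed and provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from pdxms.synthdata import TissueClass, TissueLabelMap

#: Column dictionary for cohort CSVs.  Only ``case_id`` and the outcome are
#: mandatory; unknown columns are preserved untouched.
COLUMN_DICTIONARY = {
    "case_id": "unique case identifier",
    "age": "age at diagnosis, years",
    "subtype": "receptor subtype: HER2+ | HR+ | HR+/HER2+ | TNBC",
    "ki67": "Ki-67 labeling index, percent on the 10-step grid {0,10,...,90}",
    "nac": "neoadjuvant chemotherapy given: yes | no",
    "diagnosis": "histological diagnosis (IDC | Other | ...)",
    "size_cm": "invasive tumour size, cm",
    "lvi": "lymphovascular invasion: present | not identified",
    "n_pos_ln": "number of positive lymph nodes",
    "til_pct": "stromal TIL percentage (10-step grid)",
    "hg": "histologic grade: 2 | 3",
    "pT": "pathological T category",
    "pN": "pathological N category",
    "M": "metastasis category",
    "stage": "AJCC stage",
    "miller_payne": "Miller-Payne response grade 1-5 (NAC cases only)",
    "rcb_score": "residual cancer burden score (NAC cases only)",
    "rcb_class": "residual cancer burden class (NAC cases only)",
    "AP": "intratumoral adipose proportion, x10,000",
    "BP": "intratumoral background proportion, x10,000",
    "NP": "intratumoral necrosis proportion, x10,000",
    "TDLUP": "intratumoral TDLU proportion, x10,000",
    "SP": "intratumoral stroma proportion, x10,000",
    "carcinomaP": "uncorrected intratumoral carcinoma proportion, x10,000",
    "ICP": "invasive carcinoma proportion = carcinomaP x invasive_fraction",
    "TILP": "intratumoral lymphocyte area proportion, x10,000",
    "invasive_fraction": "pathologist-assessed invasive fraction in [0,1]",
    "engrafted": "PDX engraftment success: 1 | 0",
}

PROPORTION_COLUMNS = ("AP", "BP", "NP", "TDLUP", "SP", "carcinomaP", "ICP",
                      "TILP")


class CohortValidationError(ValueError):
    """Carries a structured list of (row, column, reason) failures."""

    def __init__(self, failures: list[tuple[object, str, str]]):
        self.failures = failures
        lines = [f"  row {r}, column {c}: {why}" for r, c, why in failures[:20]]
        more = "" if len(failures) <= 20 else f"\n  ... {len(failures) - 20} more"
        super().__init__("cohort validation failed:\n" + "\n".join(lines) + more)


def validate_cohort(table: pd.DataFrame, outcome: str = "engrafted",
                    require_outcome: bool = True) -> None:
    failures: list[tuple[object, str, str]] = []
    if "case_id" not in table.columns:
        failures.append(("-", "case_id", "mandatory column missing"))
    elif table["case_id"].duplicated().any():
        dups = table.loc[table["case_id"].duplicated(), "case_id"].tolist()
        failures.append(("-", "case_id", f"duplicate ids {dups[:5]}"))
    if require_outcome and outcome not in table.columns:
        failures.append(("-", outcome, "mandatory outcome column missing"))
    if outcome in table.columns:
        bad = ~table[outcome].isin([0, 1])
        for idx in table.index[bad]:
            failures.append((idx, outcome, "outcome must be 0 or 1"))
    if "ki67" in table.columns:
        vals = table["ki67"].dropna()
        bad = vals[(vals % 10 != 0) | (vals < 0) | (vals > 90)]
        for idx, v in bad.items():
            failures.append((idx, "ki67",
                             f"{v!r} not on the 10-step grid {{0,10,...,90}}"))
    for col in PROPORTION_COLUMNS:
        if col not in table.columns:
            continue
        vals = table[col].dropna()
        bad = vals[(vals < 0) | (vals > 10000)]
        for idx, v in bad.items():
            failures.append((idx, col, f"{v!r} outside [0, 10000]"))
    if "invasive_fraction" in table.columns:
        vals = table["invasive_fraction"].dropna()
        bad = vals[(vals < 0) | (vals > 1)]
        for idx, v in bad.items():
            failures.append((idx, "invasive_fraction", f"{v!r} outside [0, 1]"))
    if "nac" in table.columns:
        no_nac = table["nac"].astype(str) == "no"
        for col in ("miller_payne", "rcb_score", "rcb_class"):
            if col not in table.columns:
                continue
            bad = no_nac & table[col].notna()
            for idx in table.index[bad]:
                failures.append((idx, col, "must be empty when nac=no"))
    if failures:
        raise CohortValidationError(failures)


def read_cohort(path: str | Path, outcome: str = "engrafted",
                require_outcome: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV (unknown columns preserved)."""
    table = pd.read_csv(path)
    validate_cohort(table, outcome=outcome, require_outcome=require_outcome)
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# label map rasters


def write_label_map(label_map: TissueLabelMap, directory: str | Path,
                    stem: str = "map", seed: int | None = None) -> None:
    """Write labels.png (8-bit, codes 1-6), lymph.png (16-bit) and a YAML
    header into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    Image.fromarray(label_map.labels.astype(np.uint8), mode="L").save(
        directory / f"{stem}_labels.png")
    lymph16 = np.round(label_map.lymph_fraction * 65535).astype(np.uint16)
    Image.fromarray(lymph16).save(directory / f"{stem}_lymph.png")
    header = {"patch_px": int(label_map.patch_px),
              "format": "labels: 8-bit tissue codes 1-6; "
                        "lymph: uint16/65535 area fraction",
              "classes": {c.name: int(c) for c in TissueClass},
              "seed": seed}
    (directory / f"{stem}.yaml").write_text(yaml.safe_dump(header))


def read_label_map(directory: str | Path, stem: str = "map") -> TissueLabelMap:
    directory = Path(directory)
    header = yaml.safe_load((directory / f"{stem}.yaml").read_text())
    labels = np.asarray(Image.open(directory / f"{stem}_labels.png"),
                        dtype=np.uint8)
    lymph = np.asarray(Image.open(directory / f"{stem}_lymph.png"),
                       dtype=np.float64) / 65535.0
    return TissueLabelMap(labels=labels, lymph_fraction=lymph,
                          patch_px=int(header["patch_px"]))


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Pipeline-wide knobs with their conventional defaults."""

    seed: int = 0
    screen_p: float = 0.2
    cp: float = 0.03
    boot_B: int = 1000
    close_radius: int = 2
    denominator_mode: str = "all"       # "all" | "tissue"
    positive_convention: str = "ge"     # score >= cutoff is positive

    def validate(self) -> None:
        if not 0.0 < self.screen_p <= 1.0:
            raise ValueError("screen_p must lie in (0, 1]")
        if self.cp < 0:
            raise ValueError("cp must be >= 0")
        if self.boot_B < 1:
            raise ValueError("boot_B must be >= 1")
        if self.denominator_mode not in ("all", "tissue"):
            raise ValueError("denominator_mode must be 'all' or 'tissue'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
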