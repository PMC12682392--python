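"""On-disk formats and run configuration: NIfTI volumes, cohort CSV, YAML.

Volumes and masks travel as NIfTI-1 (.nii / .nii.gz) with the affine
preserved untouched; masks must be strictly binary.  Cohort tables are
UTF-8 comma-separated CSV with a documented column dictionary (see
CATEGORICAL_LEVELS): unknown categorical levels and missing required columns
are hard errors naming the offenders, unknown extra columns are kept with a
warning.  Pipeline configuration is YAML validated against PipelineConfig —
unknown keys are rejected so typos cannot silently change an analysis.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cest import DEFAULT_FIELD_MHZ, NOMINAL_OFFSETS_PPM, ParametricMap
from .cohort import CATEGORICAL_LEVELS

__all__ = [
    "PipelineConfig",
    "read_volume",
    "write_volume",
    "read_mask",
    "read_cohort_csv",
    "write_cohort_csv",
    "run_manifest",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated run configuration (YAML-loadable).

    seed is mandatory for any stochastic command; deterministic stages may
    leave it at None.
    """

    offsets_ppm: tuple = NOMINAL_OFFSETS_PPM
    echo_times_s: tuple = (0.002, 0.003, 0.004)
    b_values: tuple = (0.0, 500.0, 1000.0)
    field_mhz: float = DEFAULT_FIELD_MHZ
    percentiles: tuple = (1, 5, 10, 15, 25, 50, 75, 85, 90, 95, 99)
    alpha_normality: float = 0.05
    p_enter: float = 0.05
    p_remove: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        offs = tuple(float(o) for o in self.offsets_ppm)
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("offsets_ppm must be strictly increasing")
        if any(t <= 0 for t in self.echo_times_s):
            raise ValueError("echo times must be positive")
        if len(set(self.b_values)) < 2:
            raise ValueError("need at least 2 distinct b-values")
        for nm in ("alpha_normality", "p_enter", "p_remove"):
            v = getattr(self, nm)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{nm} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in dc_fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        for key in ("offsets_ppm", "echo_times_s", "b_values", "percentiles"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("this command is stochastic: config must set a seed")
        return int(self.seed)

    def sha256(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> tuple:
    """Load a NIfTI volume -> (data float array, affine, spacing_mm tuple)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:
        raise ValueError(f"{path}: not a readable NIfTI-1 volume ({exc})") from exc
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, img.affine, spacing


def write_volume(
    path: str | Path, data: np.ndarray, affine: np.ndarray | None = None,
    spacing_mm: tuple | None = None,
) -> None:
    """Write a float volume as NIfTI-1; the affine is stored untouched."""
    if affine is None:
        affine = np.eye(4)
        if spacing_mm is not None:
            for i, s in enumerate(spacing_mm[:3]):
                affine[i, i] = s
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Load a binary ROI mask; any value outside {0, 1} is an error."""
    data, _, _ = read_volume(path)
    uniq = np.unique(data[np.isfinite(data)])
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError(
            f"{path}: mask must be binary, found values {uniq[:5]}"
        )
    return data.astype(bool)


def read_parametric_map(path: str | Path, kind: str) -> ParametricMap:
    data, _, spacing = read_volume(path)
    return ParametricMap(data, spacing_mm=spacing, kind=kind)


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------

REQUIRED_COHORT_COLUMNS = ("patient_id", "response")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Categorical columns must use the documented level vocabulary; violations
    are reported with row numbers and column names.  Unknown extra columns
    are kept (they may be features) with a warning for non-numeric ones.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    offenders = []
    for col, levels in CATEGORICAL_LEVELS.items():
        if col not in df.columns:
            continue
        bad = ~df[col].astype(str).isin(levels)
        for idx in df.index[bad]:
            offenders.append(f"row {idx}, column {col!r}: "
                             f"{df.loc[idx, col]!r} not in {levels}")
    if offenders:
        raise ValueError(f"{path}: invalid categorical levels:\n  "
                         + "\n  ".join(offenders[:20]))
    extra = [c for c in df.columns
             if c not in CATEGORICAL_LEVELS and c != "patient_id"
             and not pd.api.types.is_numeric_dtype(df[c])]
    if extra:
        warnings.warn(f"{path}: ignoring non-numeric unknown columns {extra}",
                      stacklevel=2)
        df = df.drop(columns=extra)
    return df


def write_cohort_csv(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def run_manifest(out_dir: str | Path, stage: str, config: PipelineConfig,
                 extra: dict | None = None) -> Path:
    """Write the reproducibility manifest for one pipeline stage."""
    import aptwi
    payload = {
        "stage": stage,
        "config": asdict(config),
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "versions": {"aptwi": aptwi.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
    }
    if extra:
        payload.update(extra)
    out = Path(out_dir) / f"manifest_{stage.replace(' ', '_')}.json"
    out.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return out
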