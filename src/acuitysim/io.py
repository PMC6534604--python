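"""Subject file I/O, built-in fixtures and synthetic-subject generation.

Subject files are JSON with the schema

    {"id": str, "RE_D": float, "Cyl_D": float, "d_w_mm": float,
     "d_m_mm": float, "lambda0_nm": float,
     "zernike_osa": {"<osa index>": coefficient}}

(coefficients in lambda0 units) or a CSV coefficient table with columns
``j, n, m, value`` plus the scalar fields passed separately.  Missing
coefficients default to zero; the reference wavelength defaults to 555 nm.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from . import _tables, zernike
from .wavefront import SubjectRecord


class SubjectSchemaError(ValueError):
    """Malformed or incomplete subject file."""


def fixture_subject(subject_id: str) -> SubjectRecord:
    """One of the eight built-in calibration subjects."""
    key = subject_id.upper().replace(".", "").replace(" ", "")
    if key not in _tables.SUBJECTS:
        raise KeyError(f"unknown fixture subject {subject_id!r}; "
                       f"available: {', '.join(_tables.SUBJECTS)}")
    t = _tables.SUBJECTS[key]
    return SubjectRecord(key, t["RE_D"], t["Cyl_D"], t["d_w_mm"], t["d_m_mm"],
                         dict(t["coeffs"]))


def fixture_ids() -> tuple[str, ...]:
    return tuple(_tables.SUBJECTS)


def measured_acuity(subject_id: str) -> float:
    """Measured acuity V_m (logMAR) of a fixture subject."""
    return _tables.SUBJECTS[subject_id.upper()]["V_m"]


def reference_simulated_acuity(subject_id: str) -> float:
    """Average-neural-model acuity V_ave (logMAR) kept for regression."""
    return _tables.SUBJECTS[subject_id.upper()]["V_ave"]


def subject_to_dict(subject: SubjectRecord) -> dict:
    return {
        "id": subject.id,
        "RE_D": subject.RE_D,
        "Cyl_D": subject.Cyl_D,
        "d_w_mm": subject.d_w_mm,
        "d_m_mm": subject.d_m_mm,
        "lambda0_nm": subject.lambda0_nm,
        "zernike_osa": {str(j): c for j, c in sorted(subject.coeffs_osa.items())},
    }


def save_subject(subject: SubjectRecord, path: str | Path) -> None:
    Path(path).write_text(json.dumps(subject_to_dict(subject), indent=1))


def load_subject(path: str | Path) -> SubjectRecord:
    """Load a subject record from JSON (or a ``fixtures:ID`` reference)."""
    spath = str(path)
    if spath.startswith("fixtures:"):
        return fixture_subject(spath.split(":", 1)[1])
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise SubjectSchemaError(f"{path}: not valid JSON ({err})") from err
    return subject_from_dict(data, source=spath)


def subject_from_dict(data: dict, source: str = "<dict>") -> SubjectRecord:
    for req in ("id", "d_w_mm", "d_m_mm"):
        if req not in data:
            raise SubjectSchemaError(f"{source}: missing required field {req!r}")
    coeffs: dict[tuple[int, int], float] = {}
    for j_str, val in data.get("zernike_osa", {}).items():
        try:
            nm = zernike.osa_to_nm(int(j_str))
        except (ValueError, IndexError) as err:
            raise SubjectSchemaError(f"{source}: bad OSA index {j_str!r}") from err
        coeffs[nm] = float(val)
    try:
        return SubjectRecord(
            str(data["id"]), float(data.get("RE_D", 0.0)),
            float(data.get("Cyl_D", 0.0)), float(data["d_w_mm"]),
            float(data["d_m_mm"]), coeffs,
            float(data.get("lambda0_nm", 555.0)))
    except ValueError as err:
        raise SubjectSchemaError(f"{source}: {err}") from err


def load_coefficients_csv(path: str | Path) -> dict[tuple[int, int], float]:
    """CSV coefficient table with columns j, n, m, value (OSA indexing;
    the j column is authoritative, n and m are cross-checked)."""
    coeffs: dict[tuple[int, int], float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            j = int(row["j"])
            nm = zernike.osa_to_nm(j)
            if "n" in row and row["n"] != "" and (int(row["n"]), int(row["m"])) != nm:
                raise SubjectSchemaError(
                    f"{path}: row j={j} disagrees with its (n, m) columns")
            coeffs[nm] = float(row["value"])
    return coeffs


# ---------------------------------------------------------------------------
# synthetic subjects

#: Target total RMS (lambda0 units) per radial order at severity 1,
#: matching the spread of the calibration group: astigmatism a few tenths
#: of a wave, higher orders decaying roughly threefold per order.
_ORDER_RMS = {2: 0.35, 3: 0.30, 4: 0.12, 5: 0.04, 6: 0.015}


def generate_synthetic_subject(seed: int, severity: float = 1.0,
                               subject_id: str | None = None) -> SubjectRecord:
    """Random subject with plausible aberration structure.

    Coefficients are zero-mean Gaussian per mode, with the per-order RMS
    budget decaying with radial order so that the total higher-order RMS
    at severity 1 falls inside the range spanned by the calibration
    group.  Defocus and tilts are excluded, mirroring aberrometer output.
    Fully reproducible from the seed.
    """
    if severity < 0:
        raise ValueError("severity must be non-negative")
    rng = np.random.default_rng(seed)
    coeffs: dict[tuple[int, int], float] = {}
    for order, rms in _ORDER_RMS.items():
        modes = [(order, m) for m in range(-order, order + 1, 2)
                 if not (order == 2 and m == 0)]
        per_mode = severity * rms / np.sqrt(len(modes))
        for nm in modes:
            coeffs[nm] = float(rng.normal(0.0, per_mode))
    d_w = float(rng.uniform(4.0, 6.5))
    d_m = float(rng.uniform(3.0, min(d_w, 6.5)))
    if severity == 0:
        coeffs = {}
    return SubjectRecord(subject_id or f"SYN{seed}", 0.0, 0.0, d_w, d_m, coeffs)
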