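"""Collagen preservation quality control and isotope plausibility screens.

Bone collagen extracted for radiocarbon dating must itself be well
preserved for the date and the stable-isotope values to be trustworthy.
Two screening criteria are standard: the collagen yield (mass fraction of
extract relative to starting bone) and the atomic carbon-to-nitrogen
ratio of the extract.  The default preset accepts yield > 1% and atomic
C:N between 2.9 and 3.6 (DeNiro-style range); a stricter van
Klinken-style preset narrows C:N to 3.1-3.5.

delta13C is reported relative to vPDB, delta15N relative to AIR, both in
per mil.  A specimen whose delta15N falls below every configured human
dietary range is flagged: such a value is more plausible for a herbivorous
or omnivorous animal than for a human of the same period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

ATOMIC_MASS_C = 12.011
ATOMIC_MASS_N = 14.007


@dataclass
class CollagenRecord:
    specimen_id: str
    coll_percent: float
    d13C: float | None = None
    d15N: float | None = None
    pC: float | None = None
    pN: float | None = None
    cn_ratio: float | None = None  # atomic; computed from pC/pN when absent

    def atomic_cn(self) -> float:
        if self.cn_ratio is not None:
            return self.cn_ratio
        if self.pC is None or self.pN is None:
            raise ValueError(
                f"{self.specimen_id}: need cn_ratio or both pC and pN"
            )
        return atomic_cn_ratio(self.pC, self.pN)


@dataclass
class QCThresholds:
    min_coll_percent: float = 1.0
    cn_low: float = 2.9
    cn_high: float = 3.6
    name: str = "paper"

    def __post_init__(self):
        if not self.cn_low < self.cn_high:
            raise ValueError("cn_low must be < cn_high")


#: Named QC presets: the study's working criteria and the stricter
#: van Klinken ranges.
PRESETS = {
    "paper": QCThresholds(1.0, 2.9, 3.6, "paper"),
    "vanKlinken": QCThresholds(1.0, 3.1, 3.5, "vanKlinken"),
}


@dataclass
class QCResult:
    specimen_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)
    cn_ratio: float | None = None
    coll_percent: float | None = None
    dated_despite_failure: bool = False


def atomic_cn_ratio(pC: float, pN: float) -> float:
    """Atomic (molar) C:N ratio from mass-percent carbon and nitrogen.

    Rounding to one decimal happens only at the presentation layer.
    """
    if pN == 0:
        raise ZeroDivisionError("pN must be non-zero for a C:N ratio")
    return (pC / ATOMIC_MASS_C) / (pN / ATOMIC_MASS_N)


def collagen_qc(
    record: CollagenRecord,
    thresholds: QCThresholds | str = "paper",
    dated_despite_failure: bool = False,
) -> QCResult:
    """Pass/fail with every violated criterion listed as a reason."""
    if isinstance(thresholds, str):
        thresholds = PRESETS[thresholds]
    if record.coll_percent is None:
        raise ValueError(f"{record.specimen_id}: missing field coll_percent")
    cn = record.atomic_cn()
    reasons = []
    if not record.coll_percent > thresholds.min_coll_percent:
        reasons.append("yield below cutoff")
    if not (thresholds.cn_low <= cn <= thresholds.cn_high):
        reasons.append("C:N out of range")
    return QCResult(
        specimen_id=record.specimen_id,
        passed=not reasons,
        reasons=reasons,
        cn_ratio=cn,
        coll_percent=record.coll_percent,
        dated_despite_failure=dated_despite_failure and bool(reasons),
    )


def read_collagen_csv(path) -> list[CollagenRecord]:
    """Load a Table-1-style CSV of collagen measurements."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            CollagenRecord(
                specimen_id=str(row["specimen_id"]),
                coll_percent=float(row["coll_percent"]),
                d13C=float(row["d13C"]) if "d13C" in row and pd.notna(row["d13C"]) else None,
                d15N=float(row["d15N"]) if "d15N" in row and pd.notna(row["d15N"]) else None,
                pC=float(row["pC"]) if "pC" in row and pd.notna(row["pC"]) else None,
                pN=float(row["pN"]) if "pN" in row and pd.notna(row["pN"]) else None,
            )
        )
    return records


def bundled_reference_table() -> pd.DataFrame:
    """The shipped Riparo Mezzena collagen measurement table."""
    path = resources.files("paleoproof.data").joinpath("riparo_mezzena_collagen.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


DEFAULT_ISOTOPE_RANGES = pd.DataFrame(
    [
        # editable literature placeholders, per mil vs AIR
        {"population": "Neolithic human (Italian Peninsula)", "d15N_low": 8.0, "d15N_high": 12.0, "is_human": True},
        {"population": "Upper Palaeolithic human", "d15N_low": 10.0, "d15N_high": 15.0, "is_human": True},
        {"population": "Upper Palaeolithic herbivore/omnivore", "d15N_low": 2.0, "d15N_high": 8.0, "is_human": False},
    ]
)


def isotope_plausibility(
    record: CollagenRecord,
    reference_ranges: pd.DataFrame | None = None,
    companions: list[CollagenRecord] | None = None,
) -> dict:
    """Which configured populations could plausibly match this delta15N.

    Returns matching population labels, a ``low_for_human_diet`` flag when
    delta15N falls below all configured human ranges, and a
    ``possible_same_individual`` list of companion specimens with
    identical delta13C and delta15N.
    """
    if record.d15N is None:
        raise ValueError(f"{record.specimen_id}: d15N required")
    ranges = reference_ranges if reference_ranges is not None else DEFAULT_ISOTOPE_RANGES
    if ranges.empty:
        raise ValueError("reference_ranges must be non-empty")
    matches = [
        str(row["population"])
        for _, row in ranges.iterrows()
        if row["d15N_low"] <= record.d15N <= row["d15N_high"]
    ]
    human = ranges[ranges["is_human"]] if "is_human" in ranges else ranges
    low_for_human = bool(len(human)) and bool(
        (record.d15N < human["d15N_low"]).all()
    )
    same_individual = []
    for other in companions or []:
        if other.specimen_id == record.specimen_id:
            continue
        if (
            other.d13C is not None
            and record.d13C is not None
            and other.d13C == record.d13C
            and other.d15N == record.d15N
        ):
            same_individual.append(other.specimen_id)
    return {
        "specimen_id": record.specimen_id,
        "matching_populations": matches,
        "low_for_human_diet": low_for_human,
        "possible_same_individual": same_individual,
    }
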