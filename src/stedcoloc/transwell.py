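"""Transwell transcytosis bookkeeping: ELISA calibration and percent transport.

In the assay, protein is added at a known concentration to the donor
compartment of a Transwell (typically 100 nM in a 500 µL insert over a
1.5 mL well); after incubation both media are quantified at 450 nm against
a standard curve, and transport is reported as the percentage of the added
amount recovered in the acceptor compartment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DIRECTIONS = ("luminal_to_abluminal", "abluminal_to_luminal")


@dataclass
class StandardCurve:
    """Least-squares line absorbance = slope · concentration + intercept."""

    points: list[tuple[float, float]]  # (concentration nM, absorbance AU)
    slope: float
    intercept: float
    rss: float


@dataclass
class TranswellMeasurement:
    direction: str
    added_conc: float  # nM added to the donor compartment
    donor_volume: float  # µL
    acceptor_volume: float  # µL
    acceptor_conc: float  # nM, from the standard curve
    donor_conc: float = float("nan")  # nM remaining in the donor, if measured
    timepoint_min: float = float("nan")

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.donor_volume <= 0 or self.acceptor_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.added_conc < 0 or self.acceptor_conc < 0:
            raise ValueError("concentrations must be >= 0")


@dataclass
class TranswellResult:
    percent: float
    mass_balance: float  # recovered fraction of the added amount
    inconsistent: bool  # mass balance above tolerance => suspect input


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least-squares line through (concentration, absorbance) pairs."""
    conc = np.asarray([p[0] for p in points], dtype=float)
    absb = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("need >= 2 points with distinct concentrations")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    slope, intercept = np.polyfit(conc, absb, 1)
    resid = absb - (slope * conc + intercept)
    return StandardCurve(list(points), float(slope), float(intercept), float(resid @ resid))


def absorbance_to_conc(
    curve: StandardCurve, absorbance: float, extrapolation_margin: float = 0.1
) -> float:
    """Invert the calibration line, flooring at zero concentration.

    Absorbances outside the calibrated range by more than
    ``extrapolation_margin`` × (range width) are rejected.
    """
    if curve.slope == 0:
        raise ValueError("flat standard curve cannot be inverted")
    abs_vals = [p[1] for p in curve.points]
    lo, hi = min(abs_vals), max(abs_vals)
    margin = extrapolation_margin * (hi - lo)
    if not (lo - margin) <= absorbance <= (hi + margin):
        raise ValueError(
            f"absorbance {absorbance} outside calibrated range [{lo}, {hi}] ± {margin}"
        )
    return max(0.0, (absorbance - curve.intercept) / curve.slope)


def percent_transcytosed(
    m: TranswellMeasurement,
    reference: str = "added",
    balance_tolerance: float = 1.05,
) -> TranswellResult:
    """Percent of protein transported into the acceptor compartment.

    With ``reference='added'`` (default) the percentage is
    ``100 · (acceptor_conc · acceptor_volume) / (added_conc · donor_volume)``;
    with ``reference='recovered'`` the denominator is the total amount
    recovered in both compartments (requires a measured donor_conc).
    """
    added_amount = m.added_conc * m.donor_volume
    if added_amount == 0:
        raise ValueError("added amount is zero")
    acceptor_amount = m.acceptor_conc * m.acceptor_volume
    donor_amount = m.donor_conc * m.donor_volume
    mass_balance = (
        (acceptor_amount + donor_amount) / added_amount
        if np.isfinite(donor_amount)
        else acceptor_amount / added_amount
    )
    if reference == "added":
        percent = 100.0 * acceptor_amount / added_amount
    elif reference == "recovered":
        if not np.isfinite(donor_amount):
            raise ValueError("reference='recovered' needs a measured donor_conc")
        percent = 100.0 * acceptor_amount / (acceptor_amount + donor_amount)
    else:
        raise ValueError("reference must be 'added' or 'recovered'")
    return TranswellResult(
        percent=float(percent),
        mass_balance=float(mass_balance),
        inconsistent=bool(mass_balance > balance_tolerance),
    )


def analyze_plate(plate: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Quantify a plate table: fit standards, convert samples, add percents.

    Expected columns: sample_id, role ('standard'|'sample'), concentration
    (standards only), absorbance, compartment ('donor'|'acceptor'),
    volume_ul, timepoint_min, direction, added_conc.  Sample rows are
    matched donor/acceptor by sample_id.
    """
    if not isinstance(plate, pd.DataFrame):
        plate = pd.read_csv(plate)
    standards = plate[plate["role"] == "standard"]
    curve = fit_standard_curve(
        list(zip(standards["concentration"], standards["absorbance"]))
    )
    samples = plate[plate["role"] == "sample"].copy()
    samples["conc_nm"] = [
        absorbance_to_conc(curve, a) for a in samples["absorbance"]
    ]
    rows = []
    for sample_id, grp in samples.groupby("sample_id"):
        acceptor = grp[grp["compartment"] == "acceptor"]
        donor = grp[grp["compartment"] == "donor"]
        if acceptor.empty or donor.empty:
            raise ValueError(f"sample {sample_id!r} needs donor and acceptor rows")
        acc, don = acceptor.iloc[0], donor.iloc[0]
        m = TranswellMeasurement(
            direction=str(don.get("direction", "luminal_to_abluminal")),
            added_conc=float(don["added_conc"]),
            donor_volume=float(don["volume_ul"]),
            acceptor_volume=float(acc["volume_ul"]),
            acceptor_conc=float(acc["conc_nm"]),
            donor_conc=float(don["conc_nm"]),
            timepoint_min=float(don.get("timepoint_min", float("nan"))),
        )
        res = percent_transcytosed(m)
        rows.append(
            {
                "sample_id": sample_id,
                "direction": m.direction,
                "acceptor_conc_nm": m.acceptor_conc,
                "donor_conc_nm": m.donor_conc,
                "percent_transcytosed": res.percent,
                "mass_balance": res.mass_balance,
                "inconsistent": res.inconsistent,
            }
        )
    return pd.DataFrame(rows)
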