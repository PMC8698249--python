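"""Relative quantification of transgene expression from qRT-PCR Ct values.

Standard comparative-Ct workflow: technical replicates are averaged,
each biological replicate's target Ct is normalized to the reference
gene (dCt = Ct_target - Ct_reference), strains are differenced against
a calibrator (ddCt), and expression is reported as RQ = E^-ddCt with E
the amplification efficiency (2.0 for perfect doubling).  The
calibrator's RQ is exactly 1 by construction.  Two-strain comparisons
run an unpaired t-test on the dCt values, which are approximately
normal on the cycle scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RelativeQuantityResult",
    "collapse_technical",
    "relative_quantity",
    "compare_strains",
]

REQUIRED_COLUMNS = ("strain", "gene", "bio_rep", "tech_rep", "ct")


def _validate(measurements: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad = measurements[(measurements["ct"] <= 0) | (measurements["ct"] >= 45)]
    if not bad.empty:
        raise ValueError("Ct values must lie in (0, 45)")
    if not set(measurements["gene"]) <= {"target", "reference"}:
        raise ValueError("gene column must be 'target' or 'reference'")
    return measurements


def collapse_technical(measurements: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct over technical replicates, per (strain, biological
    replicate, gene).  Replicates missing either gene are dropped with
    a warning."""
    import warnings

    df = _validate(measurements)
    collapsed = (
        df.groupby(["strain", "bio_rep", "gene"], as_index=False)["ct"].mean()
        .pivot(index=["strain", "bio_rep"], columns="gene", values="ct")
        .reset_index()
    )
    incomplete = collapsed[collapsed[["target", "reference"]].isna().any(axis=1)]
    if not incomplete.empty:
        for row in incomplete.itertuples(index=False):
            warnings.warn(
                f"dropping replicate {row.strain}/{row.bio_rep}: missing a gene", stacklevel=2
            )
        collapsed = collapsed.dropna(subset=["target", "reference"])
    collapsed["delta_ct"] = collapsed["target"] - collapsed["reference"]
    return collapsed[["strain", "bio_rep", "target", "reference", "delta_ct"]]


@dataclass(frozen=True)
class RelativeQuantityResult:
    strain: str
    delta_ct: tuple[float, ...]
    delta_delta_ct: float
    rq: float
    rq_min: float
    rq_max: float


def relative_quantity(
    collapsed: pd.DataFrame,
    calibrator_strain: str,
    efficiency: float = 2.0,
) -> dict[str, RelativeQuantityResult]:
    """RQ = efficiency^-ddCt per strain, calibrated so the calibrator is 1.

    ddCt = mean dCt(strain) - mean dCt(calibrator).  The dispersion band
    (rq_min, rq_max) re-expresses each biological replicate's dCt
    against the calibrator mean.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must lie in (1, 2]")
    if "delta_ct" not in collapsed.columns:
        collapsed = collapse_technical(collapsed)
    strains = collapsed["strain"].unique()
    if calibrator_strain not in strains:
        raise ValueError(f"calibrator strain {calibrator_strain!r} absent from the Ct table")

    cal_mean = collapsed.loc[collapsed["strain"] == calibrator_strain, "delta_ct"].mean()
    out: dict[str, RelativeQuantityResult] = {}
    for strain in strains:
        dcts = collapsed.loc[collapsed["strain"] == strain, "delta_ct"].to_numpy()
        ddct = float(dcts.mean() - cal_mean)
        if strain == calibrator_strain:
            ddct = 0.0  # exactly, by definition of the calibrator
        per_rep = efficiency ** -(dcts - cal_mean)
        out[strain] = RelativeQuantityResult(
            strain=strain,
            delta_ct=tuple(float(x) for x in dcts),
            delta_delta_ct=ddct,
            rq=float(efficiency**-ddct),
            rq_min=float(per_rep.min()),
            rq_max=float(per_rep.max()),
        )
    return out


def compare_strains(
    delta_ct_a,
    delta_ct_b,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided unpaired t-test on dCt values of two strains.

    ``equal_var=False`` switches to Welch's test.  Degenerate input —
    identical constant groups with no variance — returns (0, 1) rather
    than NaN.
    """
    a = np.asarray(delta_ct_a, dtype=float)
    b = np.asarray(delta_ct_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 biological replicates per strain")
    if a.std() == 0 and b.std() == 0:
        if math.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
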