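"""Host-to-fungus carbon transfer from delta-13C, and association statistics.

After a 13CO2 pulse on the host plant, the carbon a fungus acquired from the
host is estimated with a two-end-member mixing model: the extraradical
mycelium (ERM) signature is a mixture of the free-living mycelium (FLM)
end member (no host carbon) and the host leaf end member (pure host carbon),

    %C acquired = 100 * (dERM - dFLM) / (dleaf - dFLM).

The mixing interpretation is isolated in :func:`percent_c_acquired` so a
formula with isotope-enrichment corrections can be swapped in if needed.
The estimate is affine-invariant: shifting all three delta values by a
constant leaves it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class IsotopeTriplet:
    """delta-13C (permil) of host leaf, ERM and FLM tissue for one replicate."""

    delta_leaf: float
    delta_erm: float
    delta_flm: float
    replicate: str = "rep1"


class CarbonTransfer(NamedTuple):
    percent: float
    within_range: bool  # False flags values outside [0, 100] (kept unclamped)


class PearsonResult(NamedTuple):
    r: float
    df: int
    p_value: float

    def __str__(self) -> str:  # the "r(df) = value" reporting convention
        return f"r({self.df}) = {self.r:.2f}, P = {self.p_value:.3g}"


class FractionRecovery(NamedTuple):
    mean_percent: float
    ci_low: float
    ci_high: float
    ci_defined: bool


def percent_c_acquired(t: IsotopeTriplet) -> CarbonTransfer:
    """Percent of fungal carbon acquired from the host (two-pool mixing).

    Undefined when the leaf and FLM end members coincide.  Values outside
    [0, 100] (possible under measurement noise) are returned unclamped with
    ``within_range=False``.
    """
    denom = t.delta_leaf - t.delta_flm
    if denom == 0.0:
        raise ZeroDivisionError(
            "delta_leaf equals delta_flm: mixing fraction undefined"
        )
    percent = 100.0 * (t.delta_erm - t.delta_flm) / denom
    return CarbonTransfer(percent=percent, within_range=0.0 <= percent <= 100.0)


def pearson_r(x, y) -> PearsonResult:
    """Sample Pearson correlation with its t-based two-sided p-value.

    Reported with df = n - 2 following the r(df) convention of correlation
    reporting (42 pairs are reported as r(40)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), df=x.size - 2, p_value=float(res.pvalue))


def recover_fraction(
    triplets: pd.DataFrame, leaf_reference: str = "group_mean"
) -> FractionRecovery:
    """Mean recovered %C over replicate triplets with a normal-approx 95% CI.

    ``triplets`` needs columns delta_leaf, delta_erm, delta_flm (one row per
    replicate).  With ``leaf_reference='group_mean'`` the leaf end member is
    averaged over the replicate group before mixing, mirroring the practice
    of referencing each sample against the mean leaf signature of its host
    group.  With n = 1 the CI is undefined and flagged.
    """
    required = {"delta_leaf", "delta_erm", "delta_flm"}
    if not required <= set(triplets.columns):
        raise ValueError(f"triplets needs columns {sorted(required)}")
    leaf = (
        np.full(len(triplets), triplets["delta_leaf"].mean())
        if leaf_reference == "group_mean"
        else triplets["delta_leaf"].to_numpy(float)
    )
    percents = np.array(
        [
            percent_c_acquired(
                IsotopeTriplet(
                    delta_leaf=float(leaf[i]),
                    delta_erm=float(row.delta_erm),
                    delta_flm=float(row.delta_flm),
                )
            ).percent
            for i, row in enumerate(triplets.itertuples(index=False))
        ]
    )
    mean = float(percents.mean())
    if percents.size < 2:
        return FractionRecovery(mean, float("nan"), float("nan"), False)
    sem = float(percents.std(ddof=1) / np.sqrt(percents.size))
    half = 1.959963984540054 * sem
    return FractionRecovery(mean, mean - half, mean + half, True)


def read_isotopes_tsv(path) -> pd.DataFrame:
    """Read the long-format isotope TSV (replicate, tissue, delta13c).

    Tissues must be leaf / ERM / FLM (case-insensitive); returns the wide
    per-replicate triplet table used by :func:`recover_fraction`.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"replicate", "tissue", "delta13c"}
    if not required <= set(df.columns):
        raise ValueError(f"isotope TSV needs columns {sorted(required)}")
    df = df.assign(tissue=df.tissue.str.lower())
    wide = df.pivot(index="replicate", columns="tissue", values="delta13c")
    missing = {"leaf", "erm", "flm"} - set(wide.columns)
    if missing:
        raise ValueError(f"missing tissues: {sorted(missing)}")
    out = wide.rename(
        columns={"leaf": "delta_leaf", "erm": "delta_erm", "flm": "delta_flm"}
    ).reset_index()
    out.columns.name = None
    return out
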