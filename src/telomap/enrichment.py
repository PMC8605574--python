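"""qPCR fold-enrichment (IP/Input normalized to a control locus) and the
telomere-healing frequency calculation.

Fold enrichment uses the IP/Input method: per replicate,
``efficiency ** (Ct_input - Ct_ip)`` for the target divided by the same
quantity for the control locus (ARO1 by default, a non-telomeric locus low
in telomere-binding proteins). Replicate statistics are mean +/- SEM
(sd/sqrt(n), n-1 sample sd) with a two-tailed two-sample Student's t-test
against the control's per-replicate folds (identically 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

QPCR_COLUMNS = ["locus", "channel", "replicate", "Ct"]


@dataclass
class EnrichmentResult:
    locus: str
    folds: np.ndarray  # per-replicate fold vs control
    mean: float
    sem: float
    n: int
    p_value: float


@dataclass
class HealingResult:
    construct: str
    colonies_total: int
    colonies_resistant: int
    frequency: Fraction  # exact percent as a rational number

    @property
    def percent(self) -> float:
        return float(self.frequency)


def ip_over_input(ct_ip: float, ct_input: float, efficiency: float = 2.0) -> float:
    """IP/Input ratio from Ct values: ``efficiency ** (Ct_input - Ct_ip)``."""
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must be in (1, 2]")
    if not (np.isfinite(ct_ip) and np.isfinite(ct_input)):
        raise ValueError("non-finite Ct")
    return float(efficiency ** (ct_input - ct_ip))


def _per_replicate_ratio(
    df: pd.DataFrame, locus: str, efficiency: float
) -> pd.Series:
    sub = df[df["locus"] == locus]
    if sub.empty:
        raise ValueError(f"locus {locus!r} not in table")
    wide = sub.pivot_table(index="replicate", columns="channel", values="Ct")
    for channel in ("IP", "Input"):
        if channel not in wide.columns or wide[channel].isna().any():
            raise ValueError(f"locus {locus!r}: missing {channel} channel Ct")
    return (efficiency ** (wide["Input"] - wide["IP"])).rename(locus)


def fold_vs_control(
    measurements: pd.DataFrame,
    target_locus: str,
    control_locus: str = "ARO1",
    efficiency: float = 2.0,
    welch: bool = False,
) -> EnrichmentResult:
    """Per-replicate fold of a target over the control locus with stats.

    Requires paired IP/Input Cts per replicate for both loci; n >= 2 for the
    SEM. The p-value is a two-tailed two-sample t-test of the target's
    per-replicate folds against the control's (identically 1); ``welch``
    switches off the equal-variance assumption.
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must be in (1, 2]")
    target = _per_replicate_ratio(measurements, target_locus, efficiency)
    control = _per_replicate_ratio(measurements, control_locus, efficiency)
    common = target.index.intersection(control.index)
    if len(common) < 2:
        raise ValueError("need >= 2 replicates with both loci measured")
    folds = (target.loc[common] / control.loc[common]).to_numpy(np.float64)
    control_folds = np.ones_like(folds)
    n = len(folds)
    mean = float(folds.mean())
    sem = float(folds.std(ddof=1) / np.sqrt(n))
    t = stats.ttest_ind(folds, control_folds, equal_var=not welch)
    p = float(t.pvalue)
    if np.isnan(p):  # both groups constant (e.g. target == control exactly)
        p = 1.0
    return EnrichmentResult(
        locus=target_locus, folds=folds, mean=mean, sem=sem, n=n, p_value=p
    )


def enrichment_table(
    measurements: pd.DataFrame,
    control_locus: str = "ARO1",
    efficiency: float = 2.0,
    welch: bool = False,
) -> pd.DataFrame:
    """Fold/SEM/p summary for every non-control locus in a Ct table."""
    rows = []
    for locus in measurements["locus"].unique():
        if locus == control_locus:
            continue
        r = fold_vs_control(measurements, locus, control_locus, efficiency, welch)
        rows.append((r.locus, r.mean, r.sem, r.n, r.p_value))
    return pd.DataFrame(rows, columns=["locus", "fold_mean", "sem", "n", "p"])


def healing_frequency(table: pd.DataFrame) -> List[HealingResult]:
    """Telomere-addition frequency per construct, as an exact percent.

    The frequency is the percentage of colonies resistant to
    alpha-aminoadipate after HO induction, kept as an exact rational
    (``100 * resistant / total``) before any formatting.
    """
    out = []
    for _, row in table.iterrows():
        total = int(row["total"])
        resistant = int(row["resistant"])
        if total <= 0:
            raise ValueError(f"construct {row['construct']!r}: zero colonies")
        if not (0 <= resistant <= total):
            raise ValueError(f"construct {row['construct']!r}: resistant out of range")
        out.append(
            HealingResult(
                construct=str(row["construct"]),
                colonies_total=total,
                colonies_resistant=resistant,
                frequency=Fraction(100 * resistant, total),
            )
        )
    return out


def read_qpcr(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return df
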