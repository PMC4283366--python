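"""Strict-clock rate calibration and divergence dating with a site-bootstrap interval.

Under a strict molecular clock with per-lineage rate ``r`` (substitutions per
site per million years), two lineages that split ``t`` Ma ago accumulate a
corrected divergence ``d = 2 r t``. Calibrating ``r`` from a sister pair of
known age therefore inverts the same relation, and the dating step is
``t_hat = d / (2 r)`` with ``d`` the mean corrected cross-lineage divergence.

Uncertainty is quantified by resampling alignment columns with replacement
(a site bootstrap). This is a sampling-variance construct over sites, *not* a
Bayesian credible interval: it ignores calibration uncertainty and genealogical
stochasticity, and is labelled as such in every report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .lineage import LineagePartition
from .seqio import Alignment
from .sitestats import ACGT, Model, PURINES, correct_distance


@dataclass(frozen=True)
class RateCalibration:
    """A substitution rate anchored on a dated sister-pair split.

    ``rate`` is in substitutions/site/Myr and satisfies
    ``rate = d_cal / (2 * t_cal)`` exactly.
    """

    rate: float
    calibration_pair: tuple[str, str] | None = None
    split_time_ma: float | None = None
    d_cal: float | None = None

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("substitution rate must be positive")
        if self.d_cal is not None and self.split_time_ma is not None:
            if not math.isclose(self.rate, self.d_cal / (2 * self.split_time_ma)):
                raise ValueError("rate inconsistent with d_cal / (2 * t_cal)")


@dataclass(frozen=True)
class TimeEstimate:
    """Point divergence time (Ma) with a site-bootstrap percentile interval."""

    t_hat: float
    interval: tuple[float, float]
    method: str
    n_reps: int
    seed: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (lo <= self.t_hat <= hi):
            raise ValueError("point estimate must lie inside its interval")
        if self.t_hat < 0:
            raise ValueError("divergence time must be non-negative")


def calibrate_rate(
    d_cal: float,
    t_cal: float,
    calibration_pair: tuple[str, str] | None = None,
) -> RateCalibration:
    """Rate from a corrected divergence observed between lineages that split ``t_cal`` Ma ago."""
    if d_cal <= 0 or t_cal <= 0:
        raise ValueError("calibration divergence and split time must be positive")
    return RateCalibration(
        rate=d_cal / (2.0 * t_cal),
        calibration_pair=calibration_pair,
        split_time_ma=t_cal,
        d_cal=d_cal,
    )


def estimate_divergence_time(d: float, cal: RateCalibration) -> float:
    """t_hat = d / (2 r) for a corrected between-lineage divergence ``d``."""
    if d < 0:
        raise ValueError("divergence must be non-negative")
    return d / (2.0 * cal.rate)


def _group_index_pairs(
    aln: Alignment, part: LineagePartition, groups: tuple[str, str]
) -> list[tuple[int, int]]:
    g, h = groups
    by_group: dict[str, list[int]] = {g: [], h: []}
    for k, rid in enumerate(aln.ids):
        lab = part.assignment.get(rid)
        if lab in by_group:
            by_group[lab].append(k)
    if not by_group[g] or not by_group[h]:
        empty = [x for x in (g, h) if not by_group[x]]
        raise ValueError(f"no sequences for group(s) {empty} in the alignment")
    return [(a, b) for a in by_group[g] for b in by_group[h]]


def _pair_site_mismatches(
    aln: Alignment, pairs: Sequence[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Per cross-pair, per site: transition and transversion indicators (n_pairs x L)."""
    arrs = [np.frombuffer(r.residues.encode(), dtype="S1") for r in aln.records]
    purine = np.array(sorted(PURINES), dtype="S1")
    ts_rows, tv_rows = [], []
    for a, b in pairs:
        diff = arrs[a] != arrs[b]
        class_a = np.isin(arrs[a], purine)
        class_b = np.isin(arrs[b], purine)
        same_class = class_a == class_b
        ts_rows.append(diff & same_class)
        tv_rows.append(diff & ~same_class)
    return np.array(ts_rows), np.array(tv_rows)


def mean_corrected_cross_distance(
    aln: Alignment, part: LineagePartition, groups: tuple[str, str], model: Model = "K2P"
) -> float:
    """Mean of per-pair corrected distances over all cross-group sequence pairs."""
    pairs = _group_index_pairs(aln, part, groups)
    ts, tv = _pair_site_mismatches(aln, pairs)
    L = aln.length
    ds = []
    for k in range(len(pairs)):
        P = float(ts[k].mean())
        Q = float(tv[k].mean())
        if model == "JC":
            ds.append(correct_distance(P + Q, "JC"))
        else:
            ds.append(correct_distance(P + Q, "K2P", P=P, Q=Q))
    return float(np.mean(ds))


def bootstrap_time(
    aln: Alignment,
    part: LineagePartition,
    groups: tuple[str, str],
    cal: RateCalibration,
    model: Model = "K2P",
    n_reps: int = 1000,
    seed: int = 0,
) -> TimeEstimate:
    """Site-bootstrap divergence time for a pair of lineages.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    recomputes the mean corrected cross-group distance and maps it through
    ``t = d / (2 r)``. The interval is the 2.5/97.5 percentile band.
    Replicates whose resampled distance sits at model saturation are dropped
    and counted; more than 10% dropped raises.
    """
    if n_reps < 100:
        raise ValueError("site bootstrap requires n_reps >= 100")
    for rec in aln.records:
        if set(rec.residues) - ACGT:
            raise ValueError("bootstrap_time requires a filtered ACGT alignment")

    pairs = _group_index_pairs(aln, part, groups)
    ts, tv = _pair_site_mismatches(aln, pairs)
    L = aln.length
    t_hat = estimate_divergence_time(
        mean_corrected_cross_distance(aln, part, groups, model), cal
    )

    rng = np.random.default_rng(seed)
    # multinomial column counts per replicate: (n_reps x L)
    counts = rng.multinomial(L, np.full(L, 1.0 / L), size=n_reps).astype(float)
    P_rep = ts.astype(float) @ counts.T / L  # (n_pairs x n_reps)
    Q_rep = tv.astype(float) @ counts.T / L

    with np.errstate(invalid="ignore", divide="ignore"):
        if model == "JC":
            p_rep = P_rep + Q_rep
            d_pair = np.where(p_rep < 0.75, -0.75 * np.log1p(-4.0 * p_rep / 3.0), np.nan)
        else:
            a1 = 1.0 - 2.0 * P_rep - Q_rep
            a2 = 1.0 - 2.0 * Q_rep
            ok = (a1 > 0) & (a2 > 0)
            d_pair = np.where(ok, -0.5 * np.log(np.where(ok, a1, 1.0)) - 0.25 * np.log(np.where(ok, a2, 1.0)), np.nan)

    d_rep = d_pair.mean(axis=0)  # NaN if any pair saturated in that replicate
    valid = ~np.isnan(d_rep)
    n_dropped = int(n_reps - valid.sum())
    if n_dropped > 0.10 * n_reps:
        raise ValueError(
            f"{n_dropped}/{n_reps} bootstrap replicates at model saturation"
        )
    t_rep = d_rep[valid] / (2.0 * cal.rate)
    lo, hi = np.percentile(t_rep, [2.5, 97.5])
    lo = min(float(lo), t_hat)
    hi = max(float(hi), t_hat)
    return TimeEstimate(
        t_hat=t_hat,
        interval=(lo, hi),
        method="site-bootstrap",
        n_reps=n_reps,
        seed=seed,
        n_dropped=n_dropped,
    )


@dataclass(frozen=True)
class RelativeRateResult:
    """Tajima one-degree-of-freedom relative-rate test for a clock between two taxa."""

    n_a_only: int
    n_b_only: int
    chi2: float | None
    p_value: float | None

    @property
    def defined(self) -> bool:
        return self.chi2 is not None


def relative_rate_check(
    aln: Alignment, ingroup_pair: tuple[str, str], outgroup: str
) -> RelativeRateResult:
    """Tajima's 1D test: compare sites where only A or only B differs from the outgroup.

    With ``m1`` sites where A alone carries a unique state (B matches the
    outgroup) and ``m2`` the symmetric count, the statistic
    ``(m1 - m2)^2 / (m1 + m2)`` is approximately chi-square with 1 df under a
    clock. Zero informative sites leave the test undefined.
    """
    ids = aln.ids
    a, b = ingroup_pair
    for label in (a, b, outgroup):
        if label not in ids:
            raise ValueError(f"sequence {label!r} not in alignment")
    if len({a, b, outgroup}) != 3:
        raise ValueError("relative-rate test needs three distinct sequences")
    sa = aln.records[ids.index(a)].residues
    sb = aln.records[ids.index(b)].residues
    so = aln.records[ids.index(outgroup)].residues
    m1 = sum(1 for x, y, o in zip(sa, sb, so) if x != y and y == o)
    m2 = sum(1 for x, y, o in zip(sa, sb, so) if x != y and x == o)
    if m1 + m2 == 0:
        return RelativeRateResult(0, 0, None, None)
    chi2 = (m1 - m2) ** 2 / (m1 + m2)
    p = float(stats.chi2.sf(chi2, df=1))
    return RelativeRateResult(m1, m2, float(chi2), p)
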