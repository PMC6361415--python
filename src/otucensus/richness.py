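"""Incidence-based OTU richness estimation.

The census treats each study as an independent sampling unit.  An OTU counts
as present in a study only if it was detected (>=1 read) in at least two
samples of that study — a deliberately aggressive filter against spurious
OTUs from sequencing errors and PCR chimeras.  From the resulting binary
OTU-by-study incidence matrix we tally the frequency counts Q_i (number of
OTUs found in exactly i studies) and feed them to a suite of nonparametric
and regression-based richness estimators: Chao2, improved Chao2 (iChao2),
the incidence coverage-based estimator (ICE), a transformed weighted linear
regression model (tWLRM), a ratio-regression estimator in the style of
breakaway, and a split variant of iChao2 that pools studies into four random
global sampling units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import SampleCountTable

logger = logging.getLogger("otucensus")

__all__ = [
    "IncidenceMatrix",
    "FrequencyCounts",
    "RichnessEstimate",
    "detection_filter",
    "incidence_from_counts",
    "frequency_counts",
    "chao2",
    "ichao2",
    "ice",
    "twlrm",
    "breakaway_ratio_regression",
    "ichao2split",
    "coverage_ratio_richness",
    "recapture_fraction",
    "accumulation_curve",
    "next_study_overlap",
    "bootstrap_se",
]


@dataclass
class IncidenceMatrix:
    """Binary OTU-by-study presence matrix; columns are sampling units."""

    presence: pd.DataFrame  # 0/1, index = OTU ids, columns = study ids

    def __post_init__(self) -> None:
        vals = self.presence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("incidence matrix must be binary")

    @property
    def n_units(self) -> int:
        return self.presence.shape[1]

    @property
    def n_otus(self) -> int:
        return self.presence.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.presence.to_numpy().sum(axis=1)


@dataclass
class FrequencyCounts:
    """Incidence frequency counts Q_1..Q_T over T sampling units."""

    q: np.ndarray  # q[i-1] = Q_i
    n_units: int

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=np.int64)
        if len(self.q) < self.n_units:
            self.q = np.concatenate(
                [self.q, np.zeros(self.n_units - len(self.q), dtype=np.int64)]
            )
        if (self.q < 0).any():
            raise ValueError("frequency counts must be nonnegative")
        if len(self.q) > self.n_units:
            raise ValueError("frequency index exceeds the number of sampling units")

    def Q(self, i: int) -> int:
        return int(self.q[i - 1]) if 1 <= i <= self.n_units else 0

    @property
    def s_obs(self) -> int:
        return int(self.q.sum())

    @property
    def total_incidences(self) -> int:
        return int((np.arange(1, self.n_units + 1) * self.q).sum())


@dataclass
class RichnessEstimate:
    method: str
    s_hat: float
    s_obs: int
    se: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.s_hat):
            raise ValueError(f"{self.method}: non-finite richness estimate")
        # every estimator adds unseen richness on top of what was observed
        if self.s_hat < self.s_obs - 1e-9:
            raise ValueError(
                f"{self.method}: estimate {self.s_hat} below observed richness {self.s_obs}"
            )


# ---------------------------------------------------------------------------
# filtering and incidence construction


def detection_filter(table: SampleCountTable) -> tuple[SampleCountTable, list[str]]:
    """Remove likely-spurious OTUs: keep only OTUs found (>=1 read) in at
    least two samples of the same study.  Returns the filtered table and the
    list of removed OTU ids.
    """
    present = table.counts.to_numpy() > 0
    keep = np.zeros(table.n_otus, dtype=bool)
    cols = np.asarray(table.sample_ids)
    studies = np.asarray([table.study_of_sample[s] for s in cols])
    for study in pd.unique(studies):
        sub = present[:, studies == study]
        keep |= sub.sum(axis=1) >= 2
    # anything with <2 reads in total cannot satisfy the rule either
    keep &= table.counts.to_numpy().sum(axis=1) >= 2
    kept_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    removed = [o for o, k in zip(table.otu_ids, keep) if not k]
    return table.subset_otus(kept_ids), removed


def incidence_from_counts(table: SampleCountTable) -> IncidenceMatrix:
    """Binary OTU-by-study presence: an OTU is present in a study iff it was
    detected in >=2 samples of that study (same rule as the detection filter,
    applied separately per study)."""
    present = table.counts.to_numpy() > 0
    cols = np.asarray(table.sample_ids)
    studies = np.asarray([table.study_of_sample[s] for s in cols])
    uniq = list(pd.unique(studies))
    out = np.zeros((table.n_otus, len(uniq)), dtype=np.int8)
    for j, study in enumerate(uniq):
        sub = present[:, studies == study]
        out[:, j] = (sub.sum(axis=1) >= 2).astype(np.int8)
    m = IncidenceMatrix(pd.DataFrame(out, index=table.otu_ids, columns=uniq))
    empty = m.row_sums() == 0
    if empty.any():
        m = IncidenceMatrix(m.presence.loc[~empty])
    return m


def frequency_counts(m: IncidenceMatrix) -> FrequencyCounts:
    """Tally Q_i = number of OTUs present in exactly i sampling units."""
    sums = m.row_sums()
    T = m.n_units
    q = np.bincount(sums, minlength=T + 1)[1:]
    fc = FrequencyCounts(q=q, n_units=T)
    # conservation of mass, asserted on every call
    assert fc.s_obs == int((sums > 0).sum())
    assert fc.total_incidences == int(sums.sum())
    return fc


# ---------------------------------------------------------------------------
# closed-form estimators


def chao2(fc: FrequencyCounts) -> RichnessEstimate:
    """Chao2 lower-bound richness estimator from Q_1 and Q_2."""
    T = fc.n_units
    if T < 2:
        raise ValueError("chao2 requires at least 2 sampling units")
    q1, q2 = fc.Q(1), fc.Q(2)
    k = (T - 1) / T
    if q2 > 0:
        s = fc.s_obs + k * q1 * q1 / (2 * q2)
    else:
        s = fc.s_obs + k * q1 * (q1 - 1) / 2  # bias-corrected form
    return RichnessEstimate("chao2", s, fc.s_obs, diagnostics={"Q1": q1, "Q2": q2})


def ichao2(fc: FrequencyCounts) -> RichnessEstimate:
    """Improved Chao2: adds a correction term based on Q_3 and Q_4.

    When Q_4 = 0 the conventional substitution Q_4 <- 1 is applied and the
    estimate flagged.
    """
    T = fc.n_units
    if T < 4:
        raise ValueError("ichao2 requires at least 4 sampling units")
    base = chao2(fc)
    q1, q2, q3, q4 = fc.Q(1), fc.Q(2), fc.Q(3), fc.Q(4)
    diag = dict(base.diagnostics, Q3=q3, Q4=q4, chao2=base.s_hat)
    if q3 == 0:
        return RichnessEstimate("ichao2", base.s_hat, fc.s_obs, diagnostics=diag)
    q4_eff = q4
    if q4 == 0:
        q4_eff = 1
        diag["q4_substituted"] = True
    extra = ((T - 3) / (4 * T)) * (q3 / q4_eff) * max(
        q1 - ((T - 3) / (2 * (T - 1))) * q2 * q3 / q4_eff, 0.0
    )
    return RichnessEstimate("ichao2", base.s_hat + extra, fc.s_obs, diagnostics=diag)


def ice(
    fc: FrequencyCounts,
    m: IncidenceMatrix | None = None,
    cutoff: int = 10,
    t_infr: int | None = None,
) -> RichnessEstimate:
    """Incidence coverage-based estimator over the infrequent OTUs (Q_1..Q_k).

    T_infr (number of units containing at least one infrequent OTU) is taken
    from the incidence matrix when given, can be supplied directly via
    ``t_infr``, and otherwise conservatively defaults to the total number of
    units.
    """
    T = fc.n_units
    k = min(cutoff, T)
    q = fc.q
    s_infr = int(q[:k].sum())
    s_freq = fc.s_obs - s_infr
    if s_infr == 0:
        return RichnessEstimate("ice", float(fc.s_obs), fc.s_obs,
                                diagnostics={"cutoff": k, "S_infr": 0})
    i = np.arange(1, k + 1)
    n_infr = int((i * q[:k]).sum())
    q1 = fc.Q(1)
    if n_infr == q1:
        raise ValueError("ice: all infrequent OTUs are uniques; coverage is zero (inestimable)")
    C = 1.0 - q1 / n_infr
    if t_infr is None:
        if m is not None:
            sums = m.row_sums()
            infreq = (sums >= 1) & (sums <= k)
            t_infr = int((m.presence.to_numpy()[infreq].sum(axis=0) > 0).sum())
        else:
            t_infr = T
    if t_infr < 2:
        raise ValueError("ice: fewer than 2 sampling units contain infrequent OTUs")
    gamma2 = max(
        (s_infr / C) * (t_infr / (t_infr - 1)) * float((i * (i - 1) * q[:k]).sum()) / n_infr**2 - 1.0,
        0.0,
    )
    s = s_freq + s_infr / C + (q1 / C) * gamma2
    return RichnessEstimate(
        "ice", s, fc.s_obs,
        diagnostics={"cutoff": k, "C": C, "gamma2": gamma2, "T_infr": t_infr,
                     "S_infr": s_infr, "S_freq": s_freq},
    )


# ---------------------------------------------------------------------------
# ratio-regression estimators


def _contiguous_tau(fc: FrequencyCounts) -> int:
    """Length of the initial run of strictly positive Q_1, Q_2, ..."""
    tau = 0
    for i in range(1, fc.n_units + 1):
        if fc.Q(i) > 0:
            tau = i
        else:
            break
    return tau


def twlrm(fc: FrequencyCounts, tau: int | None = None) -> RichnessEstimate:
    """Transformed weighted linear regression model for Q_0.

    Regresses y_i = log((i+1) Q_{i+1} / Q_i) on log(i+1) with inverse-variance
    weights w_i = (1/Q_i + 1/Q_{i+1})^{-1} (delta-method variance of a log
    count ratio), extrapolates the ratio to i = 0 and predicts
    Q_0 = Q_1 / exp(y_0).
    """
    import statsmodels.api as sm

    tau = tau if tau is not None else _contiguous_tau(fc)
    if tau < 3:
        raise ValueError(f"twlrm needs contiguous nonzero Q_1..Q_tau with tau >= 3 (got {tau})")
    i = np.arange(1, tau)
    qi = np.array([fc.Q(int(j)) for j in i], dtype=float)
    qi1 = np.array([fc.Q(int(j) + 1) for j in i], dtype=float)
    y = np.log((i + 1) * qi1 / qi)
    x = sm.add_constant(np.log(i + 1))
    w = 1.0 / (1.0 / qi + 1.0 / qi1)
    res = sm.WLS(y, x, weights=w).fit()
    y0 = float(res.params[0])  # extrapolation to i=0 (log(0+1)=0)
    q0 = fc.Q(1) / math.exp(y0)
    if q0 <= 0:
        raise ValueError("twlrm: nonpositive predicted Q_0")
    # delta method: Var(Q0) ~ Q0^2 Var(y0)
    se = q0 * float(np.sqrt(res.cov_params()[0, 0]))
    return RichnessEstimate(
        "twlrm", fc.s_obs + q0, fc.s_obs, se=se,
        diagnostics={"tau": tau, "Q0_hat": q0, "slope": float(res.params[1]),
                     "intercept": y0},
    )


def _rational(beta: np.ndarray, p: int, q: int, x: np.ndarray) -> np.ndarray:
    num = np.polyval(beta[: p + 1][::-1], x)
    den = 1.0 + (np.polyval(np.concatenate([[0.0], beta[p + 1:]])[::-1], x) if q else 0.0)
    return num / den


def breakaway_ratio_regression(
    fc: FrequencyCounts,
    tau: int | None = None,
    alpha: float = 0.05,
    n_irls: int = 3,
) -> RichnessEstimate:
    """Nonlinear ratio-regression richness estimator (breakaway style).

    Models the consecutive-count ratios y_i = (i+1) Q_{i+1} / Q_i with a
    nested family of rational (Pade-type) functions of i, fitted by
    iteratively reweighted least squares.  The lowest-order model whose
    weighted lack-of-fit test is not rejected (p > alpha) and whose predicted
    Q_0 is positive is selected; the unseen richness is Q_0 = Q_1 / y(0).
    Falls back to chao2 (with a diagnostic flag) when no model converges.
    """
    tau = tau if tau is not None else _contiguous_tau(fc)
    if tau < 4:
        raise ValueError(f"breakaway needs contiguous nonzero Q_1..Q_tau with tau >= 4 (got {tau})")
    i = np.arange(1, tau, dtype=float)
    qi = np.array([fc.Q(int(j)) for j in i], dtype=float)
    qi1 = np.array([fc.Q(int(j) + 1) for j in i], dtype=float)
    y = (i + 1) * qi1 / qi
    var0 = y**2 * (1.0 / qi + 1.0 / qi1)  # delta-method variance of a count ratio

    orders = [(0, 1), (1, 1), (1, 2), (2, 2)]
    chosen = None
    for p, q in orders:
        k = p + 1 + q
        if len(y) <= k:
            break
        beta = np.zeros(k)
        beta[0] = max(y[0], 1e-6)
        sd = np.sqrt(var0)
        try:
            for _ in range(n_irls):
                def resid(b):
                    pred = _rational(b, p, q, i)
                    bad = ~np.isfinite(pred)
                    pred = np.where(bad, 1e6, pred)
                    return (pred - y) / sd
                sol = optimize.least_squares(resid, beta, method="lm", max_nfev=5000)
                beta = sol.x
                pred = _rational(beta, p, q, i)
                if not np.all(np.isfinite(pred)) or np.any(pred <= 0):
                    raise FloatingPointError("nonpositive fitted ratios")
                sd = pred * np.sqrt(1.0 / qi + 1.0 / qi1)
        except (FloatingPointError, ValueError):
            continue
        rss = float(np.sum(((pred - y) / sd) ** 2))
        dof = len(y) - k
        pval = float(stats.chi2.sf(rss, dof)) if dof > 0 else 1.0
        y0 = float(beta[0])  # rational function at i=0 is the leading numerator coeff
        if pval > alpha and y0 > 0:
            # delta-method SE of Q0 from the covariance of beta[0]
            J = sol.jac
            try:
                cov = np.linalg.inv(J.T @ J) * max(rss / dof, 1.0) if dof > 0 else None
            except np.linalg.LinAlgError:
                cov = None
            q0 = fc.Q(1) / y0
            se = (q0 / y0) * math.sqrt(cov[0, 0]) if cov is not None else None
            chosen = (p, q, q0, se, pval, rss)
            break
    if chosen is None:
        base = chao2(fc)
        return RichnessEstimate(
            "breakaway", base.s_hat, fc.s_obs, se=base.se,
            diagnostics={"fallback": "chao2", "tau": tau},
        )
    p, q, q0, se, pval, rss = chosen
    return RichnessEstimate(
        "breakaway", fc.s_obs + q0, fc.s_obs, se=se,
        diagnostics={"order": (p, q), "tau": tau, "Q0_hat": q0,
                     "lack_of_fit_p": pval, "weighted_rss": rss},
    )


# ---------------------------------------------------------------------------
# resampling-based procedures


def _split_groups(T: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Random assignment of T units to n_groups groups, sizes differing <=1."""
    base = np.repeat(np.arange(n_groups), T // n_groups)
    rest = rng.choice(n_groups, size=T % n_groups, replace=False)
    labels = np.concatenate([base, rest])
    rng.shuffle(labels)
    return labels


def ichao2split(
    m: IncidenceMatrix,
    n_groups: int = 4,
    n_repeats: int = 100,
    seed: int | None = None,
) -> RichnessEstimate:
    """iChao2 on four random complementary study groups, averaged over repeats.

    Studies are randomly pooled into ``n_groups`` near-equal global sampling
    units (group presence = presence in any member study); iChao2 is computed
    on the resulting Q_1..Q_4 with T = n_groups.  The mean over repeats is the
    estimate, the SD over repeats the standard error.
    """
    if n_groups < 4:
        raise ValueError("ichao2split needs at least 4 groups (iChao2 uses Q_4)")
    if m.n_units < n_groups:
        raise ValueError("fewer sampling units than groups")
    rng = np.random.default_rng(seed)
    pres = m.presence.to_numpy().astype(bool)
    ests = np.empty(n_repeats)
    for rep in range(n_repeats):
        labels = _split_groups(m.n_units, n_groups, rng)
        grouped = np.stack(
            [pres[:, labels == g].any(axis=1) for g in range(n_groups)], axis=1
        )
        sums = grouped.sum(axis=1)
        q = np.bincount(sums, minlength=n_groups + 1)[1:]
        fc = FrequencyCounts(q=q, n_units=n_groups)
        ests[rep] = ichao2(fc).s_hat
    return RichnessEstimate(
        "ichao2split", float(ests.mean()), int(pres.any(axis=1).sum()),
        se=float(ests.std(ddof=1)) if n_repeats > 1 else 0.0,
        diagnostics={"n_groups": n_groups, "n_repeats": n_repeats},
    )


def coverage_ratio_richness(n_census_otus: int, recapture_rho: float) -> RichnessEstimate:
    """Total richness from census size and an independent recapture fraction:
    S = N_census / rho."""
    if not (0 < recapture_rho <= 1):
        raise ValueError("recapture fraction must lie in (0, 1]")
    return RichnessEstimate(
        "coverage_ratio", n_census_otus / recapture_rho, n_census_otus,
        diagnostics={"rho": recapture_rho},
    )


def recapture_fraction(reference_ids, mapped_ids, taxon_of=None):
    """Fraction of reference sequences recaptured by the census: |mapped|/|reference|.

    With ``taxon_of`` (map id -> taxon) the fraction is computed per taxon.
    """
    ref = set(reference_ids)
    mapped = set(mapped_ids)
    if not ref:
        raise ValueError("empty reference set")
    if not mapped <= ref:
        raise ValueError("mapped ids must be a subset of the reference ids")
    if taxon_of is None:
        return len(mapped) / len(ref)
    out: dict[str, float] = {}
    by_taxon: dict[str, list] = {}
    for rid in ref:
        by_taxon.setdefault(taxon_of[rid], []).append(rid)
    for taxon, ids in by_taxon.items():
        out[taxon] = sum(1 for rid in ids if rid in mapped) / len(ids)
    return out


def accumulation_curve(
    m: IncidenceMatrix, n_repeats: int = 100, seed: int | None = None
) -> pd.DataFrame:
    """Sample-based accumulation curve: for each N = 1..T, the mean and SD
    (over random subsets of N studies) of the number of OTUs present in at
    least one chosen study."""
    rng = np.random.default_rng(seed)
    pres = m.presence.to_numpy().astype(bool)
    T = m.n_units
    rows = []
    for N in range(1, T + 1):
        if N == T:
            vals = np.full(n_repeats, pres.any(axis=1).sum(), dtype=float)
        else:
            vals = np.empty(n_repeats)
            for rep in range(n_repeats):
                cols = rng.choice(T, size=N, replace=False)
                vals[rep] = pres[:, cols].any(axis=1).sum()
        rows.append((N, float(vals.mean()), float(vals.std(ddof=0))))
    return pd.DataFrame(rows, columns=["n_studies", "mean_otus", "sd_otus"])


def next_study_overlap(
    m: IncidenceMatrix, n_repeats: int = 100, seed: int | None = None
) -> float:
    """Expected fraction of a new study's OTUs already present elsewhere.

    Over repeats: hold out one random study, compute the fraction of its OTUs
    present in at least one of the remaining T-1 studies; report the mean.
    Held-out studies containing no OTUs are skipped with a log message.
    """
    if m.n_units < 2:
        raise ValueError("need at least 2 sampling units")
    rng = np.random.default_rng(seed)
    pres = m.presence.to_numpy().astype(bool)
    fracs = []
    skipped = 0
    for _ in range(n_repeats):
        j = int(rng.integers(m.n_units))
        members = pres[:, j]
        if not members.any():
            skipped += 1
            continue
        rest = np.delete(pres, j, axis=1).any(axis=1)
        fracs.append(float((members & rest).sum() / members.sum()))
    if skipped:
        logger.info("next_study_overlap: skipped %d empty held-out studies", skipped)
    if not fracs:
        raise ValueError("all held-out studies were empty")
    return float(np.mean(fracs))


def bootstrap_se(
    m: IncidenceMatrix,
    estimator,
    n_reps: int = 200,
    seed: int | None = None,
) -> float:
    """Studies-bootstrap standard error: resample study columns with
    replacement, re-tally frequency counts, re-apply the estimator."""
    rng = np.random.default_rng(seed)
    pres = m.presence.to_numpy()
    vals = []
    for _ in range(n_reps):
        cols = rng.integers(m.n_units, size=m.n_units)
        boot = IncidenceMatrix(
            pd.DataFrame(pres[:, cols], index=m.presence.index,
                         columns=range(m.n_units))
        )
        nonzero = boot.row_sums() > 0
        boot = IncidenceMatrix(boot.presence.loc[nonzero])
        try:
            vals.append(estimator(frequency_counts(boot)).s_hat)
        except ValueError:
            continue
    if len(vals) < 2:
        raise ValueError("bootstrap failed on nearly all replicates")
    return float(np.std(vals, ddof=1))
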