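"""Procrustes ANOVA on aligned shape coordinates via RRPP.

Shape variation across the frames of a lick cycle is tested with a linear
model on the full multivariate set of Procrustes coordinates.  Sums of
squares are traces of cross-product differences between nested model fits
(Goodall-style statistics), which keeps the approach usable at the high
variable-to-observation ratios typical of geometric morphometrics.
Significance comes from residual randomization permutation procedures
(RRPP): for each term, residuals of the reduced (null) model are permuted,
added back to the null fitted values, and the statistic is recomputed.

Type III sums of squares are used for tests (full model vs. full model
minus the term); R^2 values are reported from the sequential decomposition
with blocking factors entered first, which separates estimation from
testing explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .morphometry import LandmarkVarianceProfile, ProcrustesResult, gpa_align


class AliasedFactorsError(ValueError):
    """Raised when model terms are collinear (aliased)."""


@dataclass
class ShapeAnovaResult:
    """Per-term SS/df/MS/R^2/F/Z/p for a multivariate shape model."""

    table: pd.DataFrame
    ss_total: float
    ss_residual: float
    df_residual: int
    n_perm: int
    seed: int | None

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def r_squared(self, name: str) -> float:
        return float(self.table.loc[name, "R2"])

    def p_value(self, name: str) -> float:
        return float(self.table.loc[name, "p_perm"])


def _dummy(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded (drop-first) indicator columns for a factor."""
    levels = list(dict.fromkeys(labels.tolist()))
    if len(levels) < 2:
        raise ValueError("each tested factor needs >= 2 levels")
    cols = [np.asarray(labels == lev, dtype=float) for lev in levels[1:]]
    return np.column_stack(cols)


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def _rss(resid_proj: np.ndarray, y: np.ndarray) -> float:
    return float(((resid_proj @ y) ** 2).sum())


def procrustes_anova(response: np.ndarray | ProcrustesResult,
                     factors: Mapping[str, Sequence],
                     blocks: Sequence[str] = (),
                     n_perm: int = 9999,
                     seed: int | None = None,
                     perm_chunk: int = 200) -> ShapeAnovaResult:
    """Multivariate shape ANOVA with RRPP permutation tests.

    Parameters
    ----------
    response:
        (n, p) matrix of aligned shape coordinates (rows = frames), or a
        :class:`ProcrustesResult` whose flattened coordinates are used.
    factors:
        Mapping of factor name to an n-vector of labels (e.g. ``frame``
        ordinal labels and ``cycle`` block labels).
    blocks:
        Factor names entered first in the sequential decomposition used
        for R^2 reporting.  All terms are tested with type III SS.
    n_perm:
        Number of residual permutations; the observed statistic is counted
        among them, so p >= 1/(n_perm + 1).
    """
    if isinstance(response, ProcrustesResult):
        y = response.flat()
    else:
        y = np.asarray(response, dtype=float)
    n = y.shape[0]
    names = list(factors)
    order = [b for b in blocks if b in names] + [t for t in names
                                                if t not in blocks]
    labels = {t: np.asarray(factors[t]) for t in order}
    for t in order:
        if labels[t].shape[0] != n:
            raise ValueError(f"factor {t!r} must label all {n} rows")
    term_cols = {t: _dummy(labels[t]) for t in order}

    intercept = np.ones((n, 1))
    x_full = np.column_stack([intercept] + [term_cols[t] for t in order])
    rank_full = np.linalg.matrix_rank(x_full)
    expected = 1 + sum(c.shape[1] for c in term_cols.values())
    if rank_full < expected:
        aliased = []
        running = intercept
        for t in order:
            cand = np.column_stack([running, term_cols[t]])
            if np.linalg.matrix_rank(cand) < running.shape[1] + term_cols[t].shape[1]:
                aliased.append(t)
            running = cand
        raise AliasedFactorsError(
            f"aliased (collinear) terms: {', '.join(aliased) or 'unknown'}"
        )
    if n <= expected:
        raise ValueError("more parameters than observations")

    h_full = _hat(x_full)
    i_full = np.eye(n) - h_full
    rss_full = _rss(i_full, y)
    ss_total = float(((y - y.mean(axis=0)) ** 2).sum())
    df_resid = n - rank_full

    # sequential decomposition (blocks first) for R^2
    seq_ss = {}
    running = intercept
    rss_prev = ss_total
    for t in order:
        running = np.column_stack([running, term_cols[t]])
        rss_t = _rss(np.eye(n) - _hat(running), y)
        seq_ss[t] = rss_prev - rss_t
        rss_prev = rss_t

    rng = np.random.default_rng(seed)
    rows = []
    for t in order:
        others = [intercept] + [term_cols[u] for u in order if u != t]
        x_red = np.column_stack(others)
        h_red = _hat(x_red)
        i_red = np.eye(n) - h_red
        rss_red = _rss(i_red, y)
        ss_t = rss_red - rss_full
        df_t = term_cols[t].shape[1]
        f_obs = (ss_t / df_t) / (rss_full / df_resid)

        # RRPP: permute reduced-model residuals, add back null fits
        fit0 = h_red @ y
        resid0 = y - fit0
        f_perm = np.empty(n_perm)
        done = 0
        while done < n_perm:
            chunk = min(perm_chunk, n_perm - done)
            perms = np.stack([rng.permutation(n) for _ in range(chunk)])
            y_star = fit0[None] + resid0[perms]          # (c, n, p)
            rss_red_s = np.einsum(
                "ij,cjp->cip", i_red, y_star, optimize=True
            )
            rss_full_s = np.einsum(
                "ij,cjp->cip", i_full, y_star, optimize=True
            )
            rr = (rss_red_s ** 2).sum(axis=(1, 2))
            rf = (rss_full_s ** 2).sum(axis=(1, 2))
            f_perm[done:done + chunk] = ((rr - rf) / df_t) / (rf / df_resid)
            done += chunk
        count = int(np.sum(f_perm >= f_obs))
        p = (1 + count) / (1 + n_perm)
        logf = np.log(np.maximum(f_perm, 1e-300))
        sd = logf.std(ddof=1)
        z = (np.log(max(f_obs, 1e-300)) - logf.mean()) / sd if sd > 0 else np.nan
        rows.append(
            {
                "term": t,
                "df": df_t,
                "SS": ss_t,
                "MS": ss_t / df_t,
                "R2": seq_ss[t] / ss_total if ss_total > 0 else np.nan,
                "F": f_obs,
                "Z": z,
                "p_perm": p,
            }
        )
    rows.append(
        {
            "term": "residual",
            "df": df_resid,
            "SS": rss_full,
            "MS": rss_full / df_resid,
            "R2": rss_full / ss_total if ss_total > 0 else np.nan,
            "F": np.nan,
            "Z": np.nan,
            "p_perm": np.nan,
        }
    )
    rows.append(
        {
            "term": "total",
            "df": n - 1,
            "SS": ss_total,
            "MS": np.nan,
            "R2": 1.0,
            "F": np.nan,
            "Z": np.nan,
            "p_perm": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    return ShapeAnovaResult(
        table=table,
        ss_total=ss_total,
        ss_residual=rss_full,
        df_residual=df_resid,
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# tracking repeatability
# ---------------------------------------------------------------------------

@dataclass
class RepeatabilityResult:
    """Repeatability ANOVA plus per-landmark tracking-error variance."""

    anova: ShapeAnovaResult
    error_profile: LandmarkVarianceProfile


def repeatability_test(configs, frame_labels, dataset_labels,
                       n_perm: int = 999, seed: int | None = None,
                       ) -> RepeatabilityResult:
    """Quantify landmark-tracking error from replicate trackings.

    ``configs`` holds replicate trackings of the same frames (an
    (m, k, 2) array or FrameConfiguration sequence); ``dataset_labels``
    identifies the tracking replicate (observer x attempt) and
    ``frame_labels`` the underlying video frame.  All replicates are
    GPA-aligned collectively, a Procrustes ANOVA is run with dataset as a
    blocking factor, and the per-landmark error-variance profile
    (S^2 across replicates within each frame, summarized across frames
    with a 95% CI) is returned for juxtaposition with lick-cycle variance.
    """
    frame_labels = np.asarray(frame_labels)
    dataset_labels = np.asarray(dataset_labels)
    datasets = list(dict.fromkeys(dataset_labels.tolist()))
    if len(datasets) < 2:
        raise ValueError("need >= 2 tracking replicates")
    ref = sorted(frame_labels[dataset_labels == datasets[0]].tolist())
    for d in datasets[1:]:
        if sorted(frame_labels[dataset_labels == d].tolist()) != ref:
            raise ValueError(f"replicate {d!r} covers a different frame set")

    result = gpa_align(configs)
    anova = procrustes_anova(
        result,
        factors={"dataset": dataset_labels, "frame": frame_labels},
        blocks=("dataset",),
        n_perm=n_perm,
        seed=seed,
    )
    # error variance: across replicates within each frame
    profile = _error_profile(result, frame_labels)
    return RepeatabilityResult(anova=anova, error_profile=profile)


def _error_profile(result: ProcrustesResult, frame_labels) -> LandmarkVarianceProfile:
    labels = np.asarray(frame_labels)
    frames = list(dict.fromkeys(labels.tolist()))
    per = []
    for f in frames:
        sub = result.aligned[labels == f]
        per.append(sub.var(axis=0, ddof=1).sum(axis=1))
    per = np.stack(per)
    mean = per.mean(axis=0)
    nf = per.shape[0]
    if nf >= 2:
        sem = per.std(axis=0, ddof=1) / np.sqrt(nf)
        tcrit = _sps.t.ppf(0.975, df=nf - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    else:
        lo = hi = None
    return LandmarkVarianceProfile(
        per_group_s2=per, mean_s2=mean, ci_low=lo, ci_high=hi,
        group_ids=tuple(frames),
    )


def bending_zone_flags(lick: LandmarkVarianceProfile,
                       error: LandmarkVarianceProfile) -> np.ndarray:
    """Landmarks whose lick-cycle variance exceeds tracking error.

    A landmark is flagged as mobile when its lick-cycle S^2 CI lies
    entirely above the tracking-error S^2 CI (non-overlapping 95% CIs).
    """
    if lick.ci_low is None or error.ci_high is None:
        raise ValueError("both profiles need confidence intervals")
    return lick.ci_low > error.ci_high
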