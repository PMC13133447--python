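"""TRF component extraction, behavioral scoring, and group statistics.

Component conventions follow the auditory evoked-response literature: the
sensory TRF-N1 is the global minimum of the frontal-central envelope kernel
in 50-150 ms and TRF-P2 the global maximum in 150-250 ms; the semantic
TRF-N400 is the global minimum of the parietal surprisal-kernel *difference*
wave (high-surprisal condition minus control) in 200-1000 ms, its amplitude
averaged over a 20 ms window around the peak.

Inferential tools cover the designs used around those components: Welch
t-tests with Cohen's d and noncentral-t confidence intervals, one-sided
Wilcoxon signed-rank tests, a 1-between x 2-within mixed ANOVA by
partitioned sums of squares, Spearman correlations with Benjamini-Hochberg
FDR, chi-square on 2x2 tables, and the minimum detectable effect size of a
two-sample t-test (sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .trf import TRFModel

__all__ = [
    "ROI_FRONTOCENTRAL",
    "ROI_PARIETAL",
    "PeakMeasure",
    "BehavioralScores",
    "StatResult",
    "roi_waveform",
    "extract_sensory_peaks",
    "extract_n400",
    "score_listening_span",
    "score_ssq",
    "welch_t",
    "wilcoxon_signed_rank",
    "mixed_anova",
    "spearman_fdr",
    "chi_square_2x2",
    "min_detectable_effect",
]

#: Default sensory ROI: six frontal-central electrodes.
ROI_FRONTOCENTRAL = ["F3", "Fz", "F4", "FC1", "FCz", "FC2"]
#: Default semantic ROI: nine parietal electrodes.
ROI_PARIETAL = ["CP1", "CPz", "CP2", "P3", "P1", "Pz", "P2", "P4", "POz"]


@dataclass
class PeakMeasure:
    component: str
    latency_ms: float
    amplitude: float
    window_ms: tuple[float, float]


@dataclass
class BehavioralScores:
    """Listening-span and SSQ summary scores for one participant."""

    recall_pct: float | None = None
    judgment_pct: float | None = None
    ssq_speech: float | None = None
    ssq_spatial: float | None = None
    ssq_quality: float | None = None
    ssq_all: float | None = None


@dataclass
class StatResult:
    name: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    effect: float | None = None
    effect_name: str | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    q: float | None = None
    note: str | None = None


# -- ROI waveforms and peaks ----------------------------------------------


def roi_waveform(
    trf: TRFModel, feature: str, channels: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean kernel across ROI channels for one feature: (times_ms, waveform)."""
    if not channels:
        raise ValueError("empty ROI")
    missing = [c for c in channels if c not in trf.ch_names]
    if missing:
        raise ValueError(f"ROI channels absent from model: {missing}")
    f = trf.feature_names.index(feature)
    idx = [trf.ch_names.index(c) for c in channels]
    return trf.times_ms, trf.weights[f][:, idx].mean(axis=1)


def _window_extremum(
    times: np.ndarray, wave: np.ndarray, window: tuple[float, float], kind: str
) -> tuple[float, float]:
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError(f"lag axis does not cover window {window} ms")
    w = wave[mask]
    t = times[mask]
    i = int(np.argmin(w) if kind == "min" else np.argmax(w))  # earliest on ties
    return float(t[i]), float(w[i])


def extract_sensory_peaks(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    n1_window: tuple[float, float] = (50.0, 150.0),
    p2_window: tuple[float, float] = (150.0, 250.0),
) -> dict:
    """TRF-N1 (window minimum), TRF-P2 (window maximum), and N1-P2 amplitude."""
    t1, a1 = _window_extremum(times_ms, waveform, n1_window, "min")
    t2, a2 = _window_extremum(times_ms, waveform, p2_window, "max")
    return {
        "N1": PeakMeasure("N1", t1, a1, n1_window),
        "P2": PeakMeasure("P2", t2, a2, p2_window),
        "n1p2": a2 - a1,
    }


def extract_n400(
    trf_e45: TRFModel,
    trf_control: TRFModel,
    roi: list[str],
    feature: str = "word_surprisal",
    window_ms: tuple[float, float] = (200.0, 1000.0),
    mean_halfwidth_ms: float = 10.0,
) -> PeakMeasure:
    """TRF-N400 from the condition difference wave (E45 minus Control).

    Latency is the ROI-mean difference wave's minimum within ``window_ms``;
    amplitude is the mean of that wave within +/- ``mean_halfwidth_ms``
    around the peak.
    """
    if list(trf_e45.times_ms) != list(trf_control.times_ms):
        raise ValueError("models must share a lag axis")
    times, wave_e = roi_waveform(trf_e45, feature, roi)
    _, wave_c = roi_waveform(trf_control, feature, roi)
    diff = wave_e - wave_c
    latency, _ = _window_extremum(times, diff, window_ms, "min")
    mmask = np.abs(times - latency) <= mean_halfwidth_ms
    return PeakMeasure(
        component="N400",
        latency_ms=latency,
        amplitude=float(diff[mmask].mean()),
        window_ms=window_ms,
    )


# -- behavioral scoring ----------------------------------------------------


def score_listening_span(trials: list[dict]) -> BehavioralScores:
    """Recall and sentence-judgment accuracy over listening-span blocks.

    Each trial record holds ``presented`` (words to memorize), ``recalled``
    (typed words) and ``judgments`` (booleans, correct/incorrect sentence
    plausibility decisions).  Matching is case-insensitive and exact; a
    recalled word is credited once per presented instance.
    """
    n_presented = n_recalled = n_judge = n_judge_ok = 0
    for trial in trials:
        presented = [w.strip().lower() for w in trial["presented"]]
        recalled = [w.strip().lower() for w in trial.get("recalled", [])]
        n_presented += len(presented)
        pool = list(presented)
        for w in recalled:
            if w in pool:
                pool.remove(w)
                n_recalled += 1
        judgments = trial.get("judgments", [])
        n_judge += len(judgments)
        n_judge_ok += sum(bool(j) for j in judgments)
    return BehavioralScores(
        recall_pct=100.0 * n_recalled / n_presented if n_presented else None,
        judgment_pct=100.0 * n_judge_ok / n_judge if n_judge else None,
    )


SSQ_DOMAINS = ("speech", "spatial", "quality")


def score_ssq(items: list[tuple[str, float]]) -> BehavioralScores:
    """Per-domain mean ratings (0-10) plus the overall mean."""
    by_domain: dict[str, list[float]] = {d: [] for d in SSQ_DOMAINS}
    all_ratings = []
    for domain, rating in items:
        if domain not in by_domain:
            raise ValueError(f"unknown SSQ domain {domain!r}")
        if not 0 <= rating <= 10:
            raise ValueError(f"SSQ rating out of range [0, 10]: {rating}")
        by_domain[domain].append(float(rating))
        all_ratings.append(float(rating))
    mean = lambda xs: float(np.mean(xs)) if xs else None  # noqa: E731
    return BehavioralScores(
        ssq_speech=mean(by_domain["speech"]),
        ssq_spatial=mean(by_domain["spatial"]),
        ssq_quality=mean(by_domain["quality"]),
        ssq_all=mean(all_ratings),
    )


# -- inferential statistics ------------------------------------------------


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    sp = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    return float((a.mean() - b.mean()) / sp)


def _d_ci(d: float, n1: int, n2: int, conf: float = 0.95) -> tuple[float, float]:
    """Confidence interval on Cohen's d by noncentral-t inversion."""
    scale = np.sqrt(n1 * n2 / (n1 + n2))
    df = n1 + n2 - 2
    t_obs = d * scale
    lo_q, hi_q = (1 + conf) / 2, (1 - conf) / 2

    def cdf(nc: float) -> float:
        v = sps.nct.cdf(t_obs, df, nc)
        if np.isnan(v):  # numeric underflow at extreme noncentrality
            return 0.0 if nc > t_obs else 1.0
        return float(v)

    def bound(q: float) -> float:
        lo, hi = t_obs - 20 - 10 * abs(t_obs), t_obs + 20 + 10 * abs(t_obs)
        return optimize.brentq(lambda nc: cdf(nc) - q, lo, hi) / scale

    return bound(lo_q), bound(hi_q)


def welch_t(a, b, tails: int = 2) -> StatResult:
    """Welch's unequal-variance t-test with Cohen's d (pooled SD) and 95% CI."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both samples; t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    p = res.pvalue if tails == 2 else res.pvalue / 2
    d = _cohens_d(a, b)
    lo, hi = _d_ci(d, len(a), len(b))
    return StatResult(
        name="welch_t",
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(p),
        effect=d,
        effect_name="cohens_d",
        ci_low=lo,
        ci_high=hi,
    )


def wilcoxon_signed_rank(diffs, alternative: str = "greater") -> StatResult:
    """One-sample Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; the exact null distribution is used for n <= 25
    (falling back to the tie-corrected normal approximation with continuity
    correction when ties make the exact distribution unavailable).
    The reported effect is mean(diff)/SD(diff), a d-like standardized mean
    difference (convention-dependent for rank tests).
    """
    diffs = np.asarray(diffs, dtype=float)
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        raise ValueError("all differences are zero; test undefined")
    method = "exact" if len(nz) <= 25 else "approx"
    if method == "exact" and len(np.unique(np.abs(nz))) < len(nz):
        method = "approx"  # ties: exact distribution unavailable
    res = sps.wilcoxon(
        nz, alternative=alternative, method=method, correction=(method == "approx")
    )
    effect = float(diffs.mean() / diffs.std(ddof=1)) if len(diffs) > 1 else None
    note = None if len(diffs) >= 5 else "small sample (n < 5)"
    return StatResult(
        name="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        df=None,
        p=float(res.pvalue),
        effect=effect,
        effect_name="mean_over_sd",
        note=note,
    )


def mixed_anova(
    df: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: list[str],
) -> pd.DataFrame:
    """Split-plot ANOVA: one between-subject factor, one or two within factors.

    Requires a complete balanced design (one observation per subject per
    within-cell).  Between effects are tested against subjects-within-groups;
    each within effect and its group interaction against the corresponding
    factor x subject-within-group error.  Returns a tidy table with
    effect, F, df1, df2, p.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within-subject factors supported")
    data = df[[subject, between, *within, dv]].copy()
    cells = data.groupby([subject, *within], observed=True)[dv].count()
    if (cells != 1).any():
        raise ValueError("design must have exactly one observation per cell")
    subjects = data[subject].unique()
    w_levels = [sorted(data[w].unique()) for w in within]
    if len(within) == 1:
        w_levels.append([None])
        data = data.assign(__w2__="_")
        within = [within[0], "__w2__"]
        w_levels[1] = ["_"]
    B, C = len(w_levels[0]), len(w_levels[1])
    # values[s, b, c]
    pivot = data.pivot_table(
        index=subject, columns=within, values=dv, observed=True, sort=True
    )
    cols = pd.MultiIndex.from_product(w_levels)
    pivot = pivot.reindex(columns=cols)
    if pivot.isna().any().any():
        raise ValueError("missing cells in the design")
    groups = data.drop_duplicates(subject).set_index(subject)[between]
    groups = groups.loc[pivot.index]
    vals = pivot.to_numpy().reshape(len(subjects), B, C)
    g_labels = sorted(groups.unique())
    g_idx = [np.flatnonzero((groups == g).to_numpy()) for g in g_labels]
    a = len(g_labels)
    N = vals.shape[0]

    grand = vals.mean()
    m_s = vals.mean(axis=(1, 2))
    m_g = np.array([m_s[i].mean() for i in g_idx])
    n_g = np.array([len(i) for i in g_idx])
    m_b = vals.mean(axis=(0, 2))
    m_c = vals.mean(axis=(0, 1))
    m_gb = np.stack([vals[i].mean(axis=(0, 2)) for i in g_idx])  # (a, B)
    m_gc = np.stack([vals[i].mean(axis=(0, 1)) for i in g_idx])  # (a, C)
    m_bc = vals.mean(axis=0)  # (B, C)
    m_gbc = np.stack([vals[i].mean(axis=0) for i in g_idx])  # (a, B, C)
    m_sb = vals.mean(axis=2)  # (N, B)
    m_sc = vals.mean(axis=1)  # (N, C)

    ss_total = ((vals - grand) ** 2).sum()
    ss_subj = B * C * ((m_s - grand) ** 2).sum()
    ss_group = B * C * (n_g * (m_g - grand) ** 2).sum()
    ss_err_between = ss_subj - ss_group

    rows = [("group", ss_group, a - 1, ss_err_between, N - a)]

    def within_effect(name, m_f, m_gf, m_sf, n_levels, other_count):
        ss_f = N * other_count * ((m_f - grand) ** 2).sum()
        ss_fg = other_count * sum(
            n_g[gi] * ((m_gf[gi] - m_g[gi] - m_f + grand) ** 2).sum()
            for gi in range(a)
        )
        # factor x subject within group error
        ss_err = 0.0
        for gi, idx in enumerate(g_idx):
            dev = (
                m_sf[idx]
                - m_s[idx][:, None]
                - m_gf[gi][None, :]
                + m_g[gi]
            )
            ss_err += other_count * (dev**2).sum()
        df_f = n_levels - 1
        df_err = (n_levels - 1) * (N - a)
        rows.append((name, ss_f, df_f, ss_err, df_err))
        rows.append((f"{name}:group", ss_fg, df_f * (a - 1), ss_err, df_err))
        return ss_f, ss_fg, ss_err

    name_b, name_c = (
        within[0],
        within[1] if within[1] != "__w2__" else None,
    )
    ss_b, ss_bg, ss_err_b = within_effect(name_b, m_b, m_gb, m_sb, B, C)
    used = ss_group + ss_err_between + ss_b + ss_bg + ss_err_b
    if name_c is not None:
        ss_c, ss_cg, ss_err_c = within_effect(name_c, m_c, m_gc, m_sc, C, B)
        ss_bc = N * ((m_bc - m_b[:, None] - m_c[None, :] + grand) ** 2).sum()
        ss_bcg = sum(
            n_g[gi]
            * (
                (
                    m_gbc[gi]
                    - m_gb[gi][:, None]
                    - m_gc[gi][None, :]
                    - m_bc
                    + m_g[gi]
                    + m_b[:, None]
                    + m_c[None, :]
                    - grand
                )
                ** 2
            ).sum()
            for gi in range(a)
        )
        used += ss_c + ss_cg + ss_err_c + ss_bc + ss_bcg
        ss_err_bc = ss_total - used
        df_err_bc = (B - 1) * (C - 1) * (N - a)
        rows.append((f"{name_b}:{name_c}", ss_bc, (B - 1) * (C - 1), ss_err_bc, df_err_bc))
        rows.append(
            (
                f"{name_b}:{name_c}:group",
                ss_bcg,
                (B - 1) * (C - 1) * (a - 1),
                ss_err_bc,
                df_err_bc,
            )
        )

    out = []
    for name, ss, df1, ss_err, df2 in rows:
        ms = ss / df1 if df1 > 0 else np.nan
        mse = ss_err / df2 if df2 > 0 else np.nan
        F = ms / mse if mse > 0 else 0.0
        p = float(sps.f.sf(F, df1, df2)) if df1 > 0 and df2 > 0 else np.nan
        out.append({"effect": name.replace("group", between), "F": F, "df1": df1, "df2": df2, "p": p})
    return pd.DataFrame(out)


def spearman_fdr(pairs: list[tuple[str, np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Spearman correlations with Benjamini-Hochberg q-values across the family.

    Missing values are dropped pairwise (count recorded per pair).  A
    constant variable makes rho undefined and raises an error naming the
    pair.
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    for name, x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        xs, ys = x[ok], y[ok]
        if len(xs) < 5:
            raise ValueError(f"pair {name!r}: fewer than 5 complete observations")
        if np.all(xs == xs[0]) or np.all(ys == ys[0]):
            raise ValueError(f"pair {name!r}: constant variable, rho undefined")
        rho, p = sps.spearmanr(xs, ys)
        rows.append({"pair": name, "n": int(ok.sum()), "rho": float(rho), "p": float(p)})
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def chi_square_2x2(table, continuity: bool = True) -> StatResult:
    """Pearson chi-square of independence on a 2x2 count table (df = 1)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin; chi-square undefined")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=continuity)
    return StatResult(name="chi_square", statistic=float(chi2), df=float(dof), p=float(p))


def min_detectable_effect(
    n1: int,
    n2: int,
    alpha: float = 0.05,
    power: float = 0.80,
    tails: int = 1,
) -> float:
    """Smallest Cohen's d a two-sample t-test detects at the requested power.

    Sensitivity analysis via noncentral-t root finding: the noncentrality at
    effect d is ``d * sqrt(n1*n2/(n1+n2))``; the returned d solves
    power(d) = power for the given alpha and tails.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("n1 and n2 must be >= 2")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        raise ValueError("requested power must exceed alpha")
    df = n1 + n2 - 2
    scale = np.sqrt(n1 * n2 / (n1 + n2))

    def attained(d: float) -> float:
        nc = d * scale
        if tails == 1:
            crit = sps.t.ppf(1 - alpha, df)
            return sps.nct.sf(crit, df, nc)
        crit = sps.t.ppf(1 - alpha / 2, df)
        return sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc)

    return float(optimize.brentq(lambda d: attained(d) - power, 1e-9, 20.0))
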