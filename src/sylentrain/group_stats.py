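"""Group-level statistics: PCA summaries, repeated-measures ANOVA with
Greenhouse–Geisser correction, Bonferroni post-hocs, k-means clustering of
conditions, phoneme-group aggregation, and marker↔ITPC correlations.

The ITPC PCA runs on participant x condition rows of the four harmonic
ITPC values (4/8/12/16 Hz) on the covariance matrix (shared units); the
edge-marker PCA z-scores its columns first (heterogeneous units: 1/s, ms,
unitless). Component signs are fixed so the largest-magnitude loading of
each component is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

#: Markers kept for the marker PCA: those with significant or marginally
#: significant condition-level correlations with the first ITPC component.
KEPT_MARKERS = ("md_latency", "ma_latency", "sharpness", "gini", "plateau")

#: Phoneme-group partitions of the 14 CV conditions (vowel-only excluded).
THREE_GROUP = {
    "stops": ("b", "d", "g", "k", "p", "t"),
    "fricatives_sibilants": ("f", "v", "s", "z"),
    "nasals_liquids": ("m", "n", "l", "r"),
}
FIVE_GROUP = {
    "stops": ("b", "d", "g", "k", "p", "t"),
    "fricatives": ("f", "v"),
    "sibilants": ("s", "z"),
    "nasals": ("m", "n"),
    "liquids": ("l", "r"),
}
VOICING_STOPS = {"voiced": ("b", "d", "g"), "unvoiced": ("k", "p", "t")}
VOICING_FRICATIVES = {"voiced": ("v", "z"), "unvoiced": ("f", "s")}


@dataclass
class GroupDesign:
    """Condition -> phoneme-group maps for the standard partitions."""

    partitions: dict[str, dict[str, tuple[str, ...]]] = field(
        default_factory=lambda: {
            "three_group": THREE_GROUP,
            "five_group": FIVE_GROUP,
            "voicing_stops": VOICING_STOPS,
            "voicing_fricatives": VOICING_FRICATIVES,
        }
    )

    def group_of(self, partition: str, condition: str) -> str | None:
        for g, members in self.partitions[partition].items():
            if condition in members:
                return g
        return None


@dataclass
class ComponentScores:
    loadings: np.ndarray  # variables x components
    scores: np.ndarray  # observations x components
    explained: np.ndarray  # fractions, non-increasing
    variables: list[str]


@dataclass
class AnovaReport:
    F: float
    df1: float
    df2: float
    p_uncorrected: float
    epsilon: float
    df1_gg: float
    df2_gg: float
    p_gg: float
    sphericity_violated: bool
    mauchly_W: float
    mauchly_p: float

    @property
    def p(self) -> float:
        """Corrected p when sphericity is violated, else the uncorrected one."""
        return self.p_gg if self.sphericity_violated else self.p_uncorrected


def _fix_signs(loadings: np.ndarray, scores: np.ndarray):
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return loadings, scores


def pca(matrix: np.ndarray, mode: str = "center-only",
        variables: list[str] | None = None) -> ComponentScores:
    """PCA of observations x variables via the covariance (center-only) or
    correlation (z-score) matrix; sklearn backend, deterministic solver."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 observations and 2 variables")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing or non-finite values in the PCA input")
    if mode == "z-score":
        sd = X.std(axis=0, ddof=1)
        tiny = sd <= 1e-12 * (np.abs(X).mean(axis=0) + 1.0)
        if np.any(tiny):
            bad = list(np.flatnonzero(tiny))
            names = [variables[i] if variables else str(i) for i in bad]
            raise ValueError(f"zero-variance variable(s): {', '.join(names)}")
        X = (X - X.mean(axis=0)) / sd
    elif mode != "center-only":
        raise ValueError("mode must be 'center-only' or 'z-score'")
    n_comp = min(X.shape)
    fit = PCA(n_components=n_comp, svd_solver="full").fit(X)
    loadings = fit.components_.T.copy()
    scores = fit.transform(X)
    loadings, scores = _fix_signs(loadings, scores)
    explained = fit.explained_variance_ratio_
    return ComponentScores(
        loadings, scores, explained,
        variables or [f"v{i}" for i in range(X.shape[1])],
    )


def itpc_components(table: pd.DataFrame,
                    freq_cols: tuple = (4.0, 8.0, 12.0, 16.0)) -> tuple[pd.DataFrame, ComponentScores]:
    """First two components of the harmonic ITPC values.

    ``table`` must hold one row per observation (participant x condition)
    with one column per harmonic frequency. Covariance PCA (shared units).
    The first component is expected to be a positively weighted average with
    4 Hz weighted highest; a warning is issued if the fitted loadings
    disagree.
    """
    missing = [c for c in freq_cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing ITPC frequency column(s): {missing}")
    X = table[list(freq_cols)].to_numpy(dtype=float)
    cs = pca(X, mode="center-only", variables=[str(c) for c in freq_cols])
    l1 = cs.loadings[:, 0]
    if not (np.all(l1 > 0) and np.argmax(l1) == 0):
        warnings.warn(
            "first ITPC component is not a 4 Hz-dominant positive weighting "
            f"(loadings {np.round(l1, 3)})", stacklevel=2,
        )
    out = table.copy()
    out["ITPC1"] = cs.scores[:, 0]
    out["ITPC2"] = cs.scores[:, 1]
    return out, cs


def marker_components(markers: pd.DataFrame,
                      kept: tuple[str, ...] = KEPT_MARKERS) -> tuple[pd.DataFrame, ComponentScores]:
    """First two z-score PCA components of the kept edge markers per condition."""
    missing = [c for c in kept if c not in markers.columns]
    if missing:
        raise ValueError(f"missing marker column(s): {missing}")
    X = markers[list(kept)].to_numpy(dtype=float)
    cs = pca(X, mode="z-score", variables=list(kept))
    out = markers.copy()
    out["PC1"] = cs.scores[:, 0]
    out["PC2"] = cs.scores[:, 1]
    return out, cs


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p from the t-transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the double-centered condition covariance."""
    S = np.cov(data, rowvar=False)
    Sd = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    c = data.shape[1]
    num = np.trace(Sd) ** 2
    den = (c - 1) * np.sum(Sd**2)
    if den == 0:
        return 1.0
    return float(min(1.0, num / den))


def _mauchly(data: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test (W statistic, chi-square p)."""
    n, c = data.shape
    # orthonormal contrasts orthogonal to the unit vector
    full = np.linalg.qr(np.column_stack([np.ones(c), np.eye(c)[:, : c - 1]]))[0]
    C = full[:, 1:].T  # (c-1) x c
    Sc = C @ np.cov(data, rowvar=False) @ C.T
    eig = np.linalg.eigvalsh(Sc)
    eig = np.clip(eig, 1e-300, None)
    k = c - 1
    W = float(np.prod(eig) / (np.mean(eig) ** k))
    df = k * (k + 1) // 2 - 1
    if df <= 0 or n - 1 <= k - 1:
        return W, 1.0
    f = (2 * k**2 + k + 2) / (6.0 * k * (n - 1))
    chi2 = -(1 - f) * (n - 1) * np.log(max(W, 1e-300))
    p = float(stats.chi2.sf(chi2, df))
    return W, p


def rm_anova_gg(data: np.ndarray, alpha: float = 0.05) -> AnovaReport:
    """One-way repeated-measures ANOVA (participants x conditions) with
    Greenhouse–Geisser correction applied when Mauchly's test rejects
    sphericity at ``alpha``."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    if np.any(~np.isfinite(data)):
        raise ValueError("unbalanced or missing cells")
    n, c = data.shape
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = c * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = c - 1.0, (c - 1.0) * (n - 1.0)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else np.inf
    p_unc = float(stats.f.sf(F, df1, df2))
    if c == 2:
        eps, W, p_m = 1.0, 1.0, 1.0
    else:
        eps = _gg_epsilon(data)
        W, p_m = _mauchly(data)
    p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps))
    return AnovaReport(
        F=float(F), df1=df1, df2=df2, p_uncorrected=p_unc,
        epsilon=eps, df1_gg=df1 * eps, df2_gg=df2 * eps, p_gg=p_gg,
        sphericity_violated=bool(p_m < alpha), mauchly_W=W, mauchly_p=p_m,
    )


def bonferroni_posthoc(
    data: pd.DataFrame | np.ndarray,
    pairs: list[tuple] | None = None,
) -> pd.DataFrame:
    """Paired two-tailed t-tests with Bonferroni adjustment.

    ``data`` is participants x conditions (DataFrame columns name the
    conditions); ``pairs`` defaults to all pairwise comparisons. Adjusted
    p = min(1, m * p) with m the family size.
    """
    df = pd.DataFrame(data)
    if pairs is None:
        cols = list(df.columns)
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        x, y = df[a].to_numpy(float), df[b].to_numpy(float)
        if x.size < 2:
            raise ValueError("need at least 2 paired observations")
        if np.allclose(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(x, y)
        rows.append({"a": a, "b": b, "t": float(t), "p_raw": float(p),
                     "p_bonferroni": float(min(1.0, m * p))})
    return pd.DataFrame(rows)


def kmeans_conditions(scores: np.ndarray, k: int = 3, restarts: int = 100,
                      seed: int = 0) -> np.ndarray:
    """Lloyd k-means on condition scores; best of ``restarts`` seeded inits."""
    X = np.asarray(scores, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of conditions {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    return km.fit_predict(X)


def group_aggregate(
    scores: pd.DataFrame,
    design: GroupDesign,
    partition: str,
    value_cols: tuple[str, ...] = ("ITPC1",),
    condition_col: str = "condition",
    participant_col: str = "participant",
) -> pd.DataFrame:
    """Per-group mean ± SEM of component scores, averaged within participant.

    Conditions outside the partition (e.g. the vowel-only condition for
    consonant partitions) are dropped. Unknown CV condition labels error.
    Returns a tidy frame (participant, group, value columns) suitable for
    :func:`rm_anova_gg` / :func:`bonferroni_posthoc`, with group mean and SEM
    attached as attrs['summary'].
    """
    part = design.partitions[partition]
    known = {c for members in part.values() for c in members}
    labels = set(map(str, scores[condition_col].unique()))
    vowel_like = {"V", "vowel", "v_only"}
    unknown = labels - known - vowel_like
    if unknown:
        raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    df = scores[scores[condition_col].astype(str).isin(known)].copy()
    df["group"] = [design.group_of(partition, c) for c in df[condition_col].astype(str)]
    tidy = df.groupby([participant_col, "group"], as_index=False)[list(value_cols)].mean()
    summary = tidy.groupby("group")[list(value_cols)].agg(["mean", "sem"])
    tidy.attrs["summary"] = summary
    return tidy
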