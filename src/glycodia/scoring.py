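"""Semi-supervised peak-group scoring and 2-dimensional FDR estimation.

Candidate peak groups extracted for targets and for three decoy classes
(peptide, glycan, both) carry peptide-evidence and glycan-evidence sub-score
vectors.  Two discriminant scores (D-scores) are learned — one per axis —
by iterative semi-supervised reweighting in the PyProphet style, combined by
LDA into a single score used to pick the best peak group per precursor, and
fed into a bivariate four-groups mixture model

    f_TT = pi00 f00 + pi01 f01 + pi10 f10 + pi11 f11

over (s_P, s_G), where the first index flags a null peptide and the second a
null glycan.  The decoy classes constrain the null components (the glycan
decoys mix f00/f10, the peptide decoys f00/f01, the both decoys are pure
f00), from which posterior error probabilities for "peptide null", "glycan
null", "both null" and their union are derived and turned into run-specific
and global q-values by PEP averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "LABELS",
    "learn_d_scores",
    "combine_d_scores",
    "estimate_pi",
    "storey_pi0",
    "MixtureModel2D",
    "pep_to_qvalue",
    "select_best_peak_groups",
    "score_features",
    "global_glycopeptide_qvalues",
    "report_filter",
    "ScoringResult",
]

LABELS = ("target", "peptide_decoy", "glycan_decoy", "both_decoy")

#: pseudo-target / pseudo-decoy split per learning axis: the decoy class that
#: is null only on the *other* axis joins the targets.
AXIS_GROUPS = {
    "peptide": (("target", "glycan_decoy"), ("peptide_decoy", "both_decoy")),
    "glycan": (("target", "peptide_decoy"), ("glycan_decoy", "both_decoy")),
}


def _subscore_columns(features: pd.DataFrame, axis: str) -> List[str]:
    prefix = "pep_" if axis == "peptide" else "gly_"
    cols = [c for c in features.columns if c.startswith(prefix)]
    if not cols:
        raise ValueError(f"no {prefix}* sub-score columns in feature table")
    return cols


def _auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Rank-based AUC of pos vs neg scores (Mann-Whitney)."""
    scores = np.concatenate([pos, neg])
    ranks = pd.Series(scores).rank().to_numpy()
    n_pos, n_neg = len(pos), len(neg)
    return (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _decoy_qvalues(target_scores: np.ndarray, decoy_scores: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values of targets from the decoy null (pi0 = 1)."""
    d = np.sort(decoy_scores)
    n_d = len(d)
    p = (n_d - np.searchsorted(d, target_scores, side="left") + 1) / (n_d + 1)
    order = np.argsort(p, kind="mergesort")
    m = len(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _orient(scores: np.ndarray, pos_mask: np.ndarray, neg_mask: np.ndarray) -> np.ndarray:
    """Flip sign so the decoy mean does not exceed the target mean."""
    if scores[neg_mask].mean() > scores[pos_mask].mean():
        return -scores
    return scores


def learn_d_scores(
    features: pd.DataFrame,
    axis: str,
    seed: int,
    n_iterations: int = 10,
    n_folds: int = 3,
    train_q: float = 0.01,
    min_train: int = 200,
) -> np.ndarray:
    """Learn a D-score for one axis by iterative semi-supervised LDA.

    For the peptide axis the target and glycan-decoy peak groups act as
    pseudo-targets while the peptide-decoy and both-decoy peak groups act as
    pseudo-decoys (the glycan axis swaps the roles).  Starting from the best
    single separating sub-score, each iteration selects pseudo-positives at
    decoy-estimated q < ``train_q`` and refits an LDA against the pseudo-
    decoys.  The final score is cross-fitted over ``n_folds`` folds so no
    peak group is scored by a model trained on itself, and standardized to
    zero mean / unit variance on the pseudo-decoys.

    Raises ``ValueError`` when fewer than ``min_train`` pseudo-targets or
    pseudo-decoys are available: small spectral libraries leave the learner
    and the downstream FDR estimates unreliable.
    """
    if axis not in AXIS_GROUPS:
        raise ValueError(f"axis must be 'peptide' or 'glycan', got {axis!r}")
    pos_labels, neg_labels = AXIS_GROUPS[axis]
    labels = features["label"].to_numpy()
    pos = np.isin(labels, pos_labels)
    neg = np.isin(labels, neg_labels)
    if pos.sum() < min_train or neg.sum() < min_train:
        raise ValueError(
            f"{axis} axis: {int(pos.sum())} pseudo-targets / {int(neg.sum())} "
            f"pseudo-decoys but >= {min_train} of each are required; "
            "a larger spectral library is needed for reliable learning"
        )

    cols = _subscore_columns(features, axis)
    X = features[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite sub-score values")
    rng = np.random.default_rng(seed)

    # initial direction: best single sub-score by AUC
    aucs = [abs(_auc(X[pos, j], X[neg, j]) - 0.5) for j in range(X.shape[1])]
    j0 = int(np.argmax(aucs))
    scores = _orient(X[:, j0].copy(), pos, neg)

    pseudo_pos = np.zeros(len(X), dtype=bool)
    for _ in range(n_iterations):
        q = _decoy_qvalues(scores[pos], scores[neg])
        sel = q < train_q
        if sel.sum() < 20:  # degenerate separation: fall back to the top decile
            sel = scores[pos] >= np.quantile(scores[pos], 0.9)
        pseudo_pos = np.zeros(len(X), dtype=bool)
        pseudo_pos[np.flatnonzero(pos)[sel]] = True
        lda = LinearDiscriminantAnalysis()
        lda.fit(
            np.vstack([X[pseudo_pos], X[neg]]),
            np.concatenate([np.ones(int(pseudo_pos.sum())), np.zeros(int(neg.sum()))]),
        )
        scores = _orient(lda.decision_function(X), pos, neg)

    # cross-fitted final scoring with the last pseudo-positive selection
    folds = rng.integers(0, n_folds, size=len(X))
    final = np.empty(len(X))
    for f in range(n_folds):
        hold = folds == f
        train_pos = pseudo_pos & ~hold
        train_neg = neg & ~hold
        lda = LinearDiscriminantAnalysis()
        lda.fit(
            np.vstack([X[train_pos], X[train_neg]]),
            np.concatenate([np.ones(int(train_pos.sum())), np.zeros(int(train_neg.sum()))]),
        )
        final[hold] = lda.decision_function(X[hold])
    final = _orient(final, pos, neg)
    mu, sd = final[neg].mean(), final[neg].std()
    return (final - mu) / (sd if sd > 0 else 1.0)


def combine_d_scores(
    s_p: np.ndarray, s_g: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Combined D-score: LDA projection of (s_P, s_G), targets vs all decoys.

    Falls back to the equal-weight sum when the within-class covariance is
    degenerate.
    """
    X = np.column_stack([s_p, s_g])
    y = (labels == "target").astype(int)
    pos, neg = y == 1, y == 0
    try:
        lda = LinearDiscriminantAnalysis()
        lda.fit(X, y)
        s_c = lda.decision_function(X)
        if not np.all(np.isfinite(s_c)):
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, ValueError):
        import warnings

        warnings.warn("degenerate covariance in LDA combination; using equal weights")
        s_c = s_p + s_g
    s_c = _orient(s_c, pos, neg)
    mu, sd = s_c[neg].mean(), s_c[neg].std()
    return (s_c - mu) / (sd if sd > 0 else 1.0)


def storey_pi0(
    target_scores: np.ndarray, decoy_scores: np.ndarray, lambda_: float = 0.4
) -> float:
    """Storey's null-proportion estimate from decoy-based p-values.

    p-values of the target scores are computed against the empirical decoy
    distribution; pi0 = #{p > lambda} / ((1 - lambda) * n), clipped to (0, 1].
    """
    d = np.sort(decoy_scores)
    n_d = len(d)
    p = (n_d - np.searchsorted(d, target_scores, side="left") + 1) / (n_d + 1)
    pi0 = (p > lambda_).sum() / ((1.0 - lambda_) * len(p))
    return float(min(max(pi0, 1e-6), 1.0))


def estimate_pi(
    s_p: np.ndarray,
    s_g: np.ndarray,
    s_c: np.ndarray,
    labels: np.ndarray,
    lambda_: float = 0.4,
) -> np.ndarray:
    """Estimate the four mixture proportions (pi00, pi01, pi10, pi11).

    pi_P = pi00 + pi01 (peptide-null fraction) from the peptide D-scores,
    pi_G = pi00 + pi10 from the glycan D-scores, and pi00 from the combined
    D-scores of targets vs both decoys, each by Storey's method; pi01, pi10,
    pi11 follow by subtraction, clipped to [0, 1] and renormalized so the
    four proportions sum to 1 exactly.
    """
    for lab in LABELS:
        if not np.any(labels == lab):
            raise ValueError(f"label class {lab!r} is empty")
    (p_pos, p_neg) = AXIS_GROUPS["peptide"]
    (g_pos, g_neg) = AXIS_GROUPS["glycan"]
    pi_p = storey_pi0(s_p[np.isin(labels, p_pos)], s_p[np.isin(labels, p_neg)], lambda_)
    pi_g = storey_pi0(s_g[np.isin(labels, g_pos)], s_g[np.isin(labels, g_neg)], lambda_)
    pi00 = storey_pi0(s_c[labels == "target"], s_c[labels == "both_decoy"], lambda_)

    raw = np.array([pi00, pi_p - pi00, pi_g - pi00, 1.0 - pi_p - pi_g + pi00])
    raw = np.clip(raw, 0.0, 1.0)
    total = raw.sum()
    pis = raw / total if total > 0 else np.array([1.0, 0.0, 0.0, 0.0])
    # enforce an exact unit sum (assign the rounding residual to the largest)
    residual = 1.0 - pis.sum()
    pis[int(np.argmax(pis))] += residual
    return pis


def _binned_kde(
    x: np.ndarray, y: np.ndarray,
    x_edges: np.ndarray, y_edges: np.ndarray,
    bw_x: float, bw_y: float,
) -> np.ndarray:
    """Bivariate Gaussian kernel density on a grid via binning + smoothing."""
    hist, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    dx = x_edges[1] - x_edges[0]
    dy = y_edges[1] - y_edges[0]
    dens = gaussian_filter(hist, sigma=(bw_x / dx, bw_y / dy), mode="constant")
    total = dens.sum() * dx * dy
    return dens / total if total > 0 else np.full_like(dens, 1.0 / (dens.size * dx * dy))


def _monotonize(grid: np.ndarray) -> np.ndarray:
    """Cumulative-minimum sweep: non-increasing along both (ascending score)
    axes; the isotonic projection under the product order used here."""
    out = grid.copy()
    for i in range(out.shape[0]):
        for_j = out[i]
        if i > 0:
            for_j = np.minimum(for_j, out[i - 1])
        out[i] = np.minimum.accumulate(for_j)
    return out


@dataclass
class MixtureModel2D:
    """Fitted bivariate four-groups mixture over (s_P, s_G).

    Densities are kernel estimates on a regular grid: f_tt (targets), f_dd
    (both decoys, = f00) directly, and the derived f01, f10 obtained by the
    subtraction identities with negative values clipped to zero and the
    result renormalized to unit mass.
    """

    pi: np.ndarray  # (pi00, pi01, pi10, pi11)
    p_centers: np.ndarray
    g_centers: np.ndarray
    f_tt: np.ndarray
    f00: np.ndarray
    f01: np.ndarray
    f10: np.ndarray
    bw_p: float = 1.0
    bw_g: float = 1.0
    n_targets: int = 0
    _pep_grids: Dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def fit(
        cls,
        s_p: np.ndarray,
        s_g: np.ndarray,
        labels: np.ndarray,
        pi: np.ndarray,
        grid_size: int = 128,
    ) -> "MixtureModel2D":
        def silverman(v: np.ndarray) -> float:
            return float(1.06 * v.std() * len(v) ** (-1 / 6)) or 1.0

        bw_p = silverman(s_p)
        bw_g = silverman(s_g)
        p_lo, p_hi = s_p.min() - 3 * bw_p, s_p.max() + 3 * bw_p
        g_lo, g_hi = s_g.min() - 3 * bw_g, s_g.max() + 3 * bw_g
        p_edges = np.linspace(p_lo, p_hi, grid_size + 1)
        g_edges = np.linspace(g_lo, g_hi, grid_size + 1)
        p_centers = 0.5 * (p_edges[:-1] + p_edges[1:])
        g_centers = 0.5 * (g_edges[:-1] + g_edges[1:])

        dens = {}
        for name, lab in (("tt", "target"), ("td", "glycan_decoy"),
                          ("dt", "peptide_decoy"), ("dd", "both_decoy")):
            mask = labels == lab
            dens[name] = _binned_kde(s_p[mask], s_g[mask], p_edges, g_edges, bw_p, bw_g)

        dx = (p_edges[1] - p_edges[0]) * (g_edges[1] - g_edges[0])
        pi00, pi01, pi10, pi11 = pi
        f00 = dens["dd"]

        def derive(f_obs: np.ndarray, w_null: float, w_alt: float) -> np.ndarray:
            if w_alt <= 0:
                return f_obs.copy()
            f = np.clip((f_obs - w_null * f00) / w_alt, 0.0, None)
            total = f.sum() * dx
            return f / total if total > 0 else f_obs.copy()

        f01 = derive(dens["dt"], pi00 + pi10, pi01 + pi11)
        f10 = derive(dens["td"], pi00 + pi01, pi10 + pi11)
        return cls(np.asarray(pi, dtype=float), p_centers, g_centers,
                   dens["tt"], f00, f01, f10,
                   bw_p=bw_p, bw_g=bw_g, n_targets=int((labels == "target").sum()))

    def _component_grids(self) -> Dict[str, np.ndarray]:
        if self._pep_grids:
            return self._pep_grids
        pi00, pi01, pi10, _ = self.pi
        den = np.maximum(self.f_tt, 1e-12 * self.f_tt.max())
        raw_p = (pi00 * self.f00 + pi01 * self.f01) / den
        raw_g = (pi00 * self.f00 + pi10 * self.f10) / den
        raw_pg = (pi00 * self.f00) / den
        raw_total = (pi00 * self.f00 + pi01 * self.f01 + pi10 * self.f10) / den
        grids = {"raw_p": raw_p, "raw_g": raw_g, "raw_pg": raw_pg, "raw_total": raw_total}
        # cells whose target density lies below half the peak contribution
        # of a single observation hold no data, only kernel tails: treat
        # them conservatively as PEP 1 so monotonization cannot drag the
        # estimate down from unsupported regions
        single_obs = 1.0 / (max(self.n_targets, 1) * 2.0 * np.pi * self.bw_p * self.bw_g)
        unsupported = self.f_tt < 0.5 * single_obs
        for name in ("p", "g", "pg", "total"):
            v = np.clip(grids[f"raw_{name}"], 0.0, 1.0)
            v[unsupported] = 1.0
            grids[name] = _monotonize(v)
        self._pep_grids = grids
        return grids

    def _indices(self, s_p: np.ndarray, s_g: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        ip = np.clip(np.searchsorted(self.p_centers, s_p), 0, len(self.p_centers) - 1)
        ig = np.clip(np.searchsorted(self.g_centers, s_g), 0, len(self.g_centers) - 1)
        return ip, ig

    def compute_pep(self, s_p: np.ndarray, s_g: np.ndarray) -> pd.DataFrame:
        """Posterior error probabilities at the given score pairs.

        Returns raw (unclipped, pre-monotonization) components — on which
        the inclusion-exclusion identity
        ``pep_total_raw == pep_p_raw + pep_g_raw - pep_pg_raw`` holds to
        floating-point rounding — alongside the clipped and monotonized
        values used downstream.
        """
        grids = self._component_grids()
        ip, ig = self._indices(np.asarray(s_p, float), np.asarray(s_g, float))
        out = {}
        for name in ("raw_p", "raw_g", "raw_pg", "raw_total", "p", "g", "pg", "total"):
            key = {"p": "pep_p", "g": "pep_g", "pg": "pep_pg", "total": "pep_total",
                   "raw_p": "pep_p_raw", "raw_g": "pep_g_raw",
                   "raw_pg": "pep_pg_raw", "raw_total": "pep_total_raw"}[name]
            out[key] = grids[name][ip, ig]
        return pd.DataFrame(out)


def pep_to_qvalue(peps: np.ndarray) -> np.ndarray:
    """q-values by PEP averaging.

    For a PEP threshold t the q-value is the mean PEP over the acceptance
    set {PEP <= t}; each record receives the q of the smallest acceptance
    set containing it (ties share the q of the full tie group).
    """
    peps = np.asarray(peps, dtype=float)
    n = len(peps)
    if n == 0:
        return peps.copy()
    order = np.argsort(peps, kind="mergesort")
    sorted_p = peps[order]
    cummean = np.cumsum(sorted_p) / np.arange(1, n + 1)
    last_of_tie = np.searchsorted(sorted_p, sorted_p, side="right") - 1
    q_sorted = cummean[last_of_tie]
    q = np.empty(n)
    q[order] = q_sorted
    return q


def select_best_peak_groups(df: pd.DataFrame) -> np.ndarray:
    """Mask of the best (highest combined D-score) peak group per
    (run, precursor); ties break by the earlier RT apex."""
    ranked = df.assign(_neg_s=-df["s_c"].to_numpy())
    idx = (
        ranked.sort_values(["run_id", "precursor_id", "_neg_s", "rt"],
                           kind="mergesort")
        .groupby(["run_id", "precursor_id"], sort=False)
        .head(1)
        .index
    )
    mask = np.zeros(len(df), dtype=bool)
    mask[df.index.get_indexer(idx)] = True
    return mask


@dataclass
class ScoringResult:
    table: pd.DataFrame
    pi: np.ndarray
    model: MixtureModel2D


def score_features(
    features: pd.DataFrame,
    seed: int,
    lambda_: float = 0.4,
    grid_size: int = 128,
    n_iterations: int = 10,
) -> ScoringResult:
    """Run the full per-run scoring cascade on a candidate peak-group table.

    Learns both D-scores, combines them, estimates the mixture proportions,
    fits the bivariate mixture, computes PEPs for every peak group, flags
    the best peak group per (run, precursor), and attaches run-specific
    q-values over the best target peak groups of each run.
    """
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(s % (2**31)) for s in ss.generate_state(2))
    df = features.reset_index(drop=True).copy()
    labels = df["label"].to_numpy()

    df["s_p"] = learn_d_scores(df, "peptide", s1, n_iterations=n_iterations)
    df["s_g"] = learn_d_scores(df, "glycan", s2, n_iterations=n_iterations)
    df["s_c"] = combine_d_scores(df["s_p"].to_numpy(), df["s_g"].to_numpy(), labels)

    pi = estimate_pi(df["s_p"].to_numpy(), df["s_g"].to_numpy(),
                     df["s_c"].to_numpy(), labels, lambda_)
    model = MixtureModel2D.fit(df["s_p"].to_numpy(), df["s_g"].to_numpy(),
                               labels, pi, grid_size)
    peps = model.compute_pep(df["s_p"].to_numpy(), df["s_g"].to_numpy())
    df = pd.concat([df, peps], axis=1)
    df["is_best"] = select_best_peak_groups(df)

    df["q_run"] = np.nan
    accept = df["is_best"] & (df["label"] == "target")
    for _run, sub in df.loc[accept].groupby("run_id"):
        df.loc[sub.index, "q_run"] = pep_to_qvalue(sub["pep_total"].to_numpy())
    return ScoringResult(df, pi, model)


def global_glycopeptide_qvalues(scored: pd.DataFrame) -> pd.DataFrame:
    """Global-context q-values: best peak group per glycopeptide across runs.

    Expects a scored table with a ``glycopeptide_id`` column; PEPs of the
    selected representatives are re-averaged into q-values on that reduced
    set.  Returns the representative rows with a ``q_global`` column.
    """
    best = scored[(scored["is_best"]) & (scored["label"] == "target")].copy()
    reps = (
        best.sort_values(["glycopeptide_id", "s_c"], ascending=[True, False],
                         kind="mergesort")
        .groupby("glycopeptide_id", sort=False)
        .head(1)
        .copy()
    )
    reps["q_global"] = pep_to_qvalue(reps["pep_total"].to_numpy())
    return reps


def report_filter(
    scored: pd.DataFrame,
    reps: pd.DataFrame,
    run_q: float = 0.05,
    best_run_q: float = 0.01,
    global_q: float = 0.01,
) -> pd.DataFrame:
    """Default reporting filter at glycopeptide level.

    A glycopeptide is reported when its best peak group passes ``run_q`` in
    every run it was detected in, passes ``best_run_q`` in at least one run,
    and its global q-value passes ``global_q``.
    """
    best = scored[(scored["is_best"]) & (scored["label"] == "target")]
    per_gp = best.groupby("glycopeptide_id")["q_run"].agg(["max", "min"])
    ok_runs = per_gp[(per_gp["max"] < run_q) & (per_gp["min"] < best_run_q)].index
    out = reps[reps["glycopeptide_id"].isin(ok_runs) & (reps["q_global"] < global_q)]
    return out.copy()
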