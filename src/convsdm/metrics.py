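"""Evaluation protocol for multi-species SDMs on presence-only data.

Implements the rank-based metrics used to compare the convolutional model and
the point-environment baseline:

* top-k accuracy  A_k = (1/n) Σ_i 1[r_i <= k], where r_i is the rank of the
  true species of test occurrence i in the descending score list;
* species-wise top-k accuracy  SA_{k,s}, the same indicator averaged over the
  j test occurrences of species s;
* mean top-k accuracy per species  MSA_k, the unweighted mean of SA_{k,s}
  over species present in the test set — this avoids giving frequent species
  more weight than rare ones;
* a species-balanced pseudo-absence AUC: since the data are presence-only,
  pseudo-absences for a species are drawn by first picking another species
  uniformly (among those with >= 1 test occurrence), then one of its test
  occurrences uniformly; AUC is the rank (Mann–Whitney) statistic with
  midrank tie handling, averaged over species (MeanAUC), optionally within
  regions.

Splitting uses a spatial block holdout: whole quadrats are withheld so no
test occurrence shares a quadrat with a training occurrence.

Tie rule for ranks: pessimistic — the true species is placed last among
score ties, so a constant predictor gets rank S, never rank 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "PredictionRanking",
    "MetricReport",
    "SplitAssignment",
    "rank_true_species",
    "ranks_from_scores",
    "top_k_accuracy",
    "mean_species_top_k",
    "spatial_block_split",
    "draw_pseudo_absences",
    "pseudo_absence_count",
    "species_auc",
    "mean_auc",
    "evaluate_mean_auc",
    "metric_report",
]


@dataclass
class PredictionRanking:
    occ_id: int
    species_id: int
    rank: int


@dataclass
class SplitAssignment:
    """Per-occurrence split labels plus the quadrat bookkeeping behind them."""

    split: np.ndarray  # "train" | "val" | "test" per occurrence
    quadrat: np.ndarray  # integer quadrat id per occurrence
    quadrat_size: float
    test_fraction_target: float

    @property
    def test_fraction_realized(self) -> float:
        return float(np.mean(self.split == "test"))


@dataclass
class MetricReport:
    k: int
    a_k: float
    msa_k: float
    sa_k: pd.Series
    n_occurrences: int
    species_counts: pd.Series
    n_species: int
    mean_auc: float | None = None
    mean_auc_by_region: dict = field(default_factory=dict)
    auc_by_species: pd.Series | None = None


# ---------------------------------------------------------------------------
# ranks and top-k metrics

def rank_true_species(scores: np.ndarray, true_index: int) -> int:
    """Rank of the true species in the descending score list (1-based).

    Pessimistic competition ranking: the true species is placed after every
    other species with a score >= its own, so with all scores equal the rank
    is S.
    """
    s = np.asarray(scores, dtype=float)
    if not 0 <= true_index < len(s):
        raise ValueError(f"unknown species index {true_index} for {len(s)} scores")
    t = s[true_index]
    greater = int(np.sum(s > t))
    ties = int(np.sum(s == t))  # includes the true species itself
    return greater + ties


def ranks_from_scores(score_matrix: np.ndarray, true_indices: np.ndarray) -> np.ndarray:
    """Vectorized :func:`rank_true_species` over a (n, S) score matrix."""
    s = np.asarray(score_matrix, dtype=float)
    t = s[np.arange(len(s)), true_indices]
    greater = (s > t[:, None]).sum(axis=1)
    ties = (s == t[:, None]).sum(axis=1)
    return greater + ties


def top_k_accuracy(ranks: np.ndarray, k: int) -> float:
    """A_k: fraction of test occurrences whose true-species rank is <= k."""
    r = np.asarray(ranks)
    if r.size == 0:
        raise ValueError("top-k accuracy is undefined on an empty test set")
    return float(np.mean(r <= k))


def mean_species_top_k(
    ranks: np.ndarray, species: np.ndarray, k: int
) -> tuple[pd.Series, float]:
    """(SA_{k,s} per species, MSA_k = unweighted mean over species with j >= 1)."""
    r = np.asarray(ranks)
    if r.size == 0:
        raise ValueError("mean species top-k is undefined on an empty test set")
    hit = pd.Series((r <= k).astype(float))
    sa = hit.groupby(np.asarray(species)).mean()
    return sa, float(sa.mean())


# ---------------------------------------------------------------------------
# spatial block holdout

def spatial_block_split(
    occurrences: pd.DataFrame,
    quadrat_size: float,
    test_fraction: float,
    val_fraction: float = 0.0,
    seed: int = 0,
) -> SplitAssignment:
    """Withhold whole quadrats as the test set; draw val at random from train.

    The domain is gridded into square quadrats anchored at the lower-left
    corner of the occurrence bounding box. Quadrats are drawn uniformly at
    random (seeded) and assigned wholly to test until the cumulative
    occurrence count first reaches ``test_fraction * n``; a random
    ``val_fraction`` of the remaining occurrences becomes the validation set.
    By construction no quadrat contains both train and test occurrences.
    """
    if quadrat_size <= 0:
        raise ValueError(f"quadrat size must be positive, got {quadrat_size}")
    if not 0 < test_fraction < 1:
        raise ValueError(f"test fraction must lie in (0, 1), got {test_fraction}")
    x = occurrences["x"].to_numpy(float)
    y = occurrences["y"].to_numpy(float)
    n = len(x)
    if n == 0:
        raise ValueError("no occurrences to split")

    qx = np.floor((x - x.min()) / quadrat_size).astype(int)
    qy = np.floor((y - y.min()) / quadrat_size).astype(int)
    quadrat = qx * (qy.max() + 1) + qy
    uniq, counts = np.unique(quadrat, return_counts=True)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    target = test_fraction * n
    split = np.full(n, "train", dtype=object)
    cum = 0
    test_quadrats = []
    for qi in order:
        if cum >= target:
            break
        test_quadrats.append(uniq[qi])
        cum += counts[qi]
    if cum >= n:
        warnings.warn(
            "test fraction constraint unachievable at this quadrat size; "
            "the entire occurrence set became test"
        )
    in_test = np.isin(quadrat, test_quadrats)
    split[in_test] = "test"

    train_idx = np.flatnonzero(~in_test)
    n_val = int(round(val_fraction * len(train_idx)))
    if n_val > 0:
        val_pick = rng.choice(train_idx, size=n_val, replace=False)
        split[val_pick] = "val"
    return SplitAssignment(split, quadrat, quadrat_size, test_fraction)


# ---------------------------------------------------------------------------
# pseudo-absence AUC

def pseudo_absence_count(n_presences: int) -> int:
    """Number of pseudo-absences: at least 100, or as many as the presences
    when the species has more than 100 test occurrences."""
    return max(100, n_presences)


def draw_pseudo_absences(
    target_species: int,
    test_occurrences: pd.DataFrame,
    seed: int = 0,
    n_draws: int | None = None,
) -> np.ndarray:
    """Two-stage species-balanced pseudo-absence draw; returns occ_ids.

    Each pseudo-absence is chosen by first drawing a species uniformly among
    species other than the target with at least one test occurrence, then one
    of that species' test occurrences uniformly. Draws are independent (with
    replacement across draws). The draw is species-uniform, *not*
    occurrence-uniform, so abundant species are not over-represented.
    """
    by_species = {
        sid: g["occ_id"].to_numpy()
        for sid, g in test_occurrences.groupby("species_id")
        if sid != target_species and len(g) > 0
    }
    if not by_species:
        raise ValueError(
            f"no species other than {target_species} has test occurrences"
        )
    if n_draws is None:
        n_pres = int((test_occurrences["species_id"] == target_species).sum())
        n_draws = pseudo_absence_count(n_pres)
    rng = np.random.default_rng(seed)
    eligible = list(by_species)
    sp_draws = rng.choice(len(eligible), size=n_draws, replace=True)
    return np.array(
        [rng.choice(by_species[eligible[s]]) for s in sp_draws], dtype=int
    )


def species_auc(presence_scores: np.ndarray, pseudo_absence_scores: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC with midrank tie handling."""
    pres = np.asarray(presence_scores, dtype=float)
    absn = np.asarray(pseudo_absence_scores, dtype=float)
    if pres.size == 0 or absn.size == 0:
        raise ValueError("AUC needs at least one presence and one pseudo-absence")
    ranks = rankdata(np.concatenate([pres, absn]))
    r_pres = ranks[: pres.size].sum()
    u = r_pres - pres.size * (pres.size + 1) / 2.0
    return float(u / (pres.size * absn.size))


def mean_auc(per_species_auc: dict[int, float]) -> float | None:
    """Unweighted mean AUC over species; None when no species is evaluable."""
    if not per_species_auc:
        return None
    return float(np.mean(list(per_species_auc.values())))


def evaluate_mean_auc(
    scores: np.ndarray,
    test_occurrences: pd.DataFrame,
    seed: int = 0,
    region_tags: np.ndarray | None = None,
) -> tuple[float | None, dict, pd.Series]:
    """Per-species pseudo-absence AUC, MeanAUC, and optional per-region means.

    ``scores`` is the (n_test, S) score matrix aligned with the rows of
    ``test_occurrences`` (CNN: logits; baseline: probabilities). Regional
    means restrict both presences and pseudo-absences to the region's test
    occurrences before computing each species' AUC. A region with no
    evaluable species is reported as absent, never as 0.
    """
    occ = test_occurrences.reset_index(drop=True)
    pos_of_occ = pd.Series(occ.index.to_numpy(), index=occ["occ_id"].to_numpy())

    def _per_species(sub: pd.DataFrame, sub_seed: int) -> dict[int, float]:
        out: dict[int, float] = {}
        species_ids = sorted(sub["species_id"].unique())
        if len(species_ids) < 2:
            return out
        for i, sid in enumerate(species_ids):
            pres_ids = sub.loc[sub["species_id"] == sid, "occ_id"].to_numpy()
            abs_ids = draw_pseudo_absences(sid, sub, seed=sub_seed + i)
            col = int(sid)
            pres = scores[pos_of_occ[pres_ids].to_numpy(), col]
            absn = scores[pos_of_occ[abs_ids].to_numpy(), col]
            out[sid] = species_auc(pres, absn)
        return out

    overall = _per_species(occ, seed)
    by_region: dict = {}
    if region_tags is not None:
        tags = np.asarray(region_tags)
        for j, region in enumerate(pd.unique(tags)):
            sub = occ[tags == region]
            res = _per_species(sub, seed + 10_000 * (j + 1))
            m = mean_auc(res)
            if m is not None:
                by_region[region] = m
    return mean_auc(overall), by_region, pd.Series(overall, dtype=float)


def metric_report(
    scores: np.ndarray,
    test_occurrences: pd.DataFrame,
    k: int = 30,
    seed: int = 0,
    region_tags: np.ndarray | None = None,
    auc_scores: np.ndarray | None = None,
) -> MetricReport:
    """Full evaluation: A_k, SA/MSA_k and the pseudo-absence MeanAUC.

    ``scores`` ranks species for the top-k metrics; ``auc_scores`` (defaults
    to ``scores``) is used for the AUC — pass logits for the convolutional
    model and probabilities for the baseline.
    """
    occ = test_occurrences.reset_index(drop=True)
    species = occ["species_id"].to_numpy(int)
    ranks = ranks_from_scores(scores, species)
    a_k = top_k_accuracy(ranks, k)
    sa, msa = mean_species_top_k(ranks, species, k)
    counts = occ.groupby("species_id").size()
    m_auc, by_region, per_species = evaluate_mean_auc(
        scores if auc_scores is None else auc_scores, occ, seed, region_tags
    )
    return MetricReport(
        k=k, a_k=a_k, msa_k=msa, sa_k=sa, n_occurrences=len(occ),
        species_counts=counts, n_species=len(sa), mean_auc=m_auc,
        mean_auc_by_region=by_region, auc_by_species=per_species,
    )
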