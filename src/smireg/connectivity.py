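"""Compound--disease connectivity scoring by weighted Kolmogorov-Smirnov
enrichment.

A compound's miRNA perturbation profile is the row of a compound x miRNA
matrix of upregulation probabilities; a disease signature is a pair of
miRNA sets (up- and downregulated in the disease).  Each profile is
centered to [-1, 1] (2*p_up - 1), ranked descending, and the two signature
sets are tested for enrichment at the top or bottom of the ranking with a
GSEA-style weighted running sum.  The connectivity score combines the two
enrichment statistics; a negative score means the compound's profile
reverses the disease signature (therapeutic candidate), a positive score
means it mimics it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DiseaseSignature:
    """miRNA ids up- and downregulated in a disease (disjoint sets)."""

    disease_id: str
    up_set: frozenset[str]
    down_set: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_set", frozenset(self.up_set))
        object.__setattr__(self, "down_set", frozenset(self.down_set))
        if self.up_set & self.down_set:
            raise ValueError(
                f"signature {self.disease_id!r}: up and down sets overlap: "
                f"{sorted(self.up_set & self.down_set)}"
            )


@dataclass
class ConnectivityScore:
    sm_id: str
    disease_id: str
    score: float
    es_up: float
    es_down: float
    n_ties: int = 0


@dataclass
class SmMirnaMatrix:
    """Dense compound x miRNA matrix of upregulation probabilities."""

    frame: pd.DataFrame  # rows: compound ids, columns: miRNA ids
    n_imputed: int = 0

    @property
    def sm_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.frame.columns)

    def profile(self, sm_id: str) -> pd.Series:
        if sm_id not in self.frame.index:
            raise KeyError(f"unknown compound {sm_id!r}")
        return self.frame.loc[sm_id]


def build_sm_mirna_matrix(
    predictions: list[tuple[str, str, float]],
) -> SmMirnaMatrix:
    """Assemble the dense compound x miRNA probability matrix.

    Duplicate (compound, miRNA) entries are averaged; cells never predicted
    are imputed at the neutral probability 0.5 and counted.
    """
    for sm_id, mir_id, p in predictions:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_up {p} for ({sm_id}, {mir_id}) outside [0, 1]")
    df = pd.DataFrame(predictions, columns=["sm_id", "mirna_id", "p_up"])
    if df.empty or df["sm_id"].nunique() < 1 or df["mirna_id"].nunique() < 2:
        raise ValueError("need at least one compound and two miRNAs")
    mat = df.pivot_table(index="sm_id", columns="mirna_id", values="p_up", aggfunc="mean")
    n_imputed = int(mat.isna().sum().sum())
    mat = mat.fillna(0.5).sort_index(axis=0).sort_index(axis=1)
    return SmMirnaMatrix(frame=mat, n_imputed=n_imputed)


def weighted_ks_es(
    ranked_ids: list[str],
    weights: np.ndarray,
    gene_set: set[str],
    p: float = 1.0,
) -> float:
    """Signed extremum of the weighted Kolmogorov-Smirnov running sum.

    ``ranked_ids`` is the full universe ordered by descending score with
    per-position weights.  Hits advance the running sum by
    |weight|^p / sum of hit |weight|^p; misses retreat by 1/(N - set size).
    The statistic is the running sum's most extreme value (by magnitude,
    keeping its sign).
    """
    weights = np.asarray(weights, dtype=float)
    if len(ranked_ids) != weights.shape[0]:
        raise ValueError("one weight per ranked id required")
    hits = np.array([i in gene_set for i in ranked_ids])
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranking")
    n_misses = len(ranked_ids) - n_hits
    if n_misses == 0:
        raise ValueError("gene set covers the whole ranking")
    w = np.abs(weights) ** p
    hit_total = w[hits].sum()
    if hit_total == 0:
        # all hit weights zero: fall back to unweighted steps
        step_hit = np.where(hits, 1.0 / n_hits, 0.0)
    else:
        step_hit = np.where(hits, w / hit_total, 0.0)
    step_miss = np.where(~hits, 1.0 / n_misses, 0.0)
    running = np.cumsum(step_hit - step_miss)
    extremum_idx = int(np.argmax(np.abs(running)))
    return float(running[extremum_idx])


def _ranked_profile(profile: pd.Series) -> tuple[list[str], np.ndarray, int]:
    """Rank miRNAs by centered score 2*p_up - 1 descending, ties by id."""
    centered = 2.0 * profile.astype(float) - 1.0
    order = sorted(centered.index, key=lambda m: (-centered[m], m))
    values = centered.loc[order].to_numpy()
    n_ties = int(len(values) - len(np.unique(values)))
    return order, values, n_ties


def connectivity_score(
    matrix: SmMirnaMatrix,
    sm_id: str,
    signature: DiseaseSignature,
) -> ConnectivityScore:
    """Connectivity of one compound profile against one disease signature.

    ES is computed for the signature's up-set and down-set on the
    compound's centered, descending-ranked profile; the score is
    (es_up - es_down)/2 when the two statistics disagree in sign, and 0
    otherwise (the established convention of this score family), clipped
    to [-1, 1].
    """
    profile = matrix.profile(sm_id)
    universe = set(profile.index)
    up = {m for m in signature.up_set if m in universe}
    down = {m for m in signature.down_set if m in universe}
    if not up or not down:
        raise ValueError(
            f"signature {signature.disease_id!r} has an empty effective "
            f"up or down set over the matrix columns"
        )
    ranked, weights, n_ties = _ranked_profile(profile)
    es_up = weighted_ks_es(ranked, weights, up)
    es_down = weighted_ks_es(ranked, weights, down)
    if np.sign(es_up) == np.sign(es_down):
        score = 0.0
    else:
        score = float(np.clip((es_up - es_down) / 2.0, -1.0, 1.0))
    return ConnectivityScore(
        sm_id=sm_id,
        disease_id=signature.disease_id,
        score=score,
        es_up=es_up,
        es_down=es_down,
        n_ties=n_ties,
    )


def connectivity_map(
    matrix: SmMirnaMatrix,
    signatures: list[DiseaseSignature],
) -> pd.DataFrame:
    """Compound x disease table of connectivity scores."""
    rows = {}
    for sm_id in matrix.sm_ids:
        rows[sm_id] = {
            sig.disease_id: connectivity_score(matrix, sm_id, sig).score
            for sig in signatures
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
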