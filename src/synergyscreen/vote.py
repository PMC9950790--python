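"""Candidate scoring by ensemble vote counting, binning and selection.

Every ensemble member casts a positive vote for a candidate pair when its
positive-class probability is at least 0.5.  Candidates are binned by vote
count — with R = 1000 members the bins are >500, 100-500, 1-100 and 0 votes
(read with strict ">" at the upper boundaries so they partition) — and pairs
with more than ``vote_select_threshold`` votes (default 700) are selected for
experimental follow-up.  For R != 1000 the cutpoints rescale as the same
fractions of R (0.5 and 0.1, threshold 0.7).
"""

from __future__ import annotations

import logging
from itertools import product

import numpy as np
import pandas as pd

from .io_core import RunConfig, canonical_pair
from .ensemble import ResampledEnsemble, _score_positive

logger = logging.getLogger("synergyscreen")

BIN_LABELS = ("gt500", "100to500", "1to100", "zero")


def enumerate_candidates(tcm_drugs: list[str], western_drugs: list[str],
                         ) -> list[tuple[str, str]]:
    """Full cross product of two disjoint drug-id lists, in canonical order."""
    overlap = set(tcm_drugs) & set(western_drugs)
    if overlap:
        raise ValueError(f"drug lists overlap: {sorted(overlap)}")
    return [canonical_pair(t, w) for t, w in product(tcm_drugs, western_drugs)]


def predict_votes(ensemble: ResampledEnsemble, candidate_features: pd.DataFrame,
                  ) -> pd.DataFrame:
    """Positive-vote counts per candidate pair.

    ``candidate_features`` must contain every feature column the members were
    trained on; a missing column is an error naming it.
    """
    missing = [c for c in ensemble.feature_names
               if c not in candidate_features.columns]
    if missing:
        raise ValueError(f"candidate table lacks feature(s) {missing} "
                         f"required by the ensemble")
    na_rows = candidate_features[ensemble.feature_names].isna().any(axis=1)
    if na_rows.any():
        raise ValueError("missing feature values for pairs "
                         f"{candidate_features.index[na_rows].tolist()}")
    votes = np.zeros(len(candidate_features), dtype=int)
    for member in ensemble.members:
        X = candidate_features[member.features].to_numpy(dtype=float)
        votes += (_score_positive(member.classifier, X) >= 0.5).astype(int)
    table = pd.DataFrame({"votes": votes}, index=candidate_features.index)
    logger.info("vote: scored %d candidates with %d members "
                "(max %d, median %.0f votes)", len(table), len(ensemble),
                votes.max(initial=0), float(np.median(votes)) if len(votes) else 0.0)
    return table


def bin_and_select(vote_table: pd.DataFrame, config: RunConfig,
                   n_members: int) -> pd.DataFrame:
    """Assign vote-count bins and the selection flag.

    Cutpoints are the printed absolute values for R = 1000 and the same
    fractions of R otherwise; selection is strict ``votes > threshold``.
    """
    r = n_members
    if r == 1000:
        hi, lo, threshold = 500, 100, config.vote_select_threshold
    else:
        hi = 0.5 * r
        lo = 0.1 * r
        threshold = (config.vote_select_threshold / 1000) * r
    out = vote_table.copy()
    votes = out["votes"].to_numpy()
    bins = np.where(votes > hi, "gt500",
                    np.where(votes > lo, "100to500",
                             np.where(votes >= 1, "1to100", "zero")))
    out["bin"] = pd.Categorical(bins, categories=list(BIN_LABELS))
    out["selected"] = votes > threshold
    return out


def rank_votes(vote_table: pd.DataFrame) -> pd.DataFrame:
    """Descending votes, ties broken by pair id."""
    out = vote_table.copy()
    out["_a"] = out.index.get_level_values(0)
    out["_b"] = out.index.get_level_values(1)
    out = out.sort_values(["votes", "_a", "_b"],
                          ascending=[False, True, True])
    return out.drop(columns=["_a", "_b"])


def score_candidates(ensemble: ResampledEnsemble,
                     candidate_features: pd.DataFrame,
                     config: RunConfig | None = None) -> pd.DataFrame:
    """Votes + bins + selection + ranking in one call (the `predict` stage)."""
    config = config or ensemble.config
    table = predict_votes(ensemble, candidate_features)
    table = bin_and_select(table, config, len(ensemble))
    return rank_votes(table)
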