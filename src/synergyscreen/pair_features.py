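"""The 16 pair features of the combination screen.

For a drug pair (d_A, d_B) the feature vector collects:

* ``S_FP`` — Tanimoto similarity of binary molecular fingerprints,
  A.B / (||A||^2 + ||B||^2 - A.B).
* ``S_ADME`` — Euclidean distance of min-max-normalized ADME descriptor
  vectors (a dissimilarity; kept on that scale deliberately).
* ``S_Seq{min,max,med,mean}`` — aggregates over all target cross-pairs of
  normalized Smith-Waterman local-alignment similarity
  sw(a,b) / sqrt(sw(a,a) * sw(b,b)).
* ``S_GO{min,max,med,mean}`` — aggregates of gene-level GO functional
  similarity; per target pair the best-match average (BMA) of Wang
  graph-based term similarity over the two targets' annotation sets.
* ``S_Pathway`` — cosine similarity of binary enriched-pathway membership
  vectors; the pathway universe is the set of pathways over-represented in
  the pooled target list (hypergeometric p < 0.05 and BH q < 0.05).
* ``S_PPI{min,max,med}`` — sigma(d) = 1/(1+exp(-d)) of the min/max/median
  unweighted shortest-path distance between the two target sets on the PPI
  graph; ``S_PPImean`` = sigma(<d_AB>) of the mean cross distance, and
  ``S_np`` = S_PPImean(A,B) - [S_PPImean(A,A) + S_PPImean(B,B)] / 2, a
  separation-style network proximity.

``UniverseFeaturizer`` caches the expensive target-level matrices
(sequence similarity, GO BMA similarity, PPI shortest paths) so featurizing
all pairs of a universe costs one pass over targets, not pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .io_core import (
    AMINO_ACIDS,
    FEATURE_NAMES,
    DegenerateInputError,
    DrugRecord,
    FeatureUnavailableError,
    RunConfig,
    TargetContext,
    canonical_pair,
)

logger = logging.getLogger("synergyscreen")


# ---------------------------------------------------------------------------
# elementary similarities
# ---------------------------------------------------------------------------

def tanimoto_fingerprint(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto similarity of two binary fingerprints."""
    a = np.asarray(fp_a, dtype=float)
    b = np.asarray(fp_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    if not a.any() or not b.any():
        raise DegenerateInputError("all-zero fingerprint: Tanimoto is 0/0")
    ab = float(a @ b)
    return ab / (float(a @ a) + float(b @ b) - ab)


@dataclass(frozen=True)
class AdmeNormalizer:
    """Per-slot min/max over the drug universe for min-max normalization."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def from_universe(cls, drugs: list[DrugRecord]) -> "AdmeNormalizer":
        mat = np.vstack([d.adme for d in drugs])
        lo, hi = mat.min(axis=0), mat.max(axis=0)
        n_const = int((hi == lo).sum())
        if n_const:
            logger.info("adme: %d constant descriptor slot(s) contribute 0 after "
                        "normalization", n_const)
        return cls(lo=lo, hi=hi)

    def __call__(self, adme: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        out = np.zeros_like(adme, dtype=float)
        ok = span > 0
        out[ok] = (np.asarray(adme, dtype=float)[ok] - self.lo[ok]) / span[ok]
        return out


def adme_distance(adme_a: np.ndarray, adme_b: np.ndarray,
                  normalizer: AdmeNormalizer) -> float:
    """Euclidean distance of min-max-normalized ADME descriptor vectors."""
    a = np.asarray(adme_a, dtype=float)
    b = np.asarray(adme_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"ADME length mismatch: {a.size} vs {b.size}")
    return float(np.linalg.norm(normalizer(a) - normalizer(b)))


# ---------------------------------------------------------------------------
# sequence similarity (Smith-Waterman)
# ---------------------------------------------------------------------------

def _make_aligner(matrix: str | None, gap_open: float, gap_extend: float,
                  match: float | None, mismatch: float | None) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if match is not None:
        aligner.match_score = match
        aligner.mismatch_score = mismatch if mismatch is not None else -match
    else:
        aligner.substitution_matrix = substitution_matrices.load(matrix or "BLOSUM62")
    # Biopython's open_gap_score applies to the first gapped position
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _validate_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    for i, ch in enumerate(seq):
        if ch not in AMINO_ACIDS:
            raise ValueError(f"{name}: unknown residue {ch!r} at position {i}")


def sw_similarity(seq_a: str, seq_b: str, *, matrix: str | None = "BLOSUM62",
                  gap_open: float = 10.0, gap_extend: float = 0.5,
                  match: float | None = None, mismatch: float | None = None) -> float:
    """Normalized Smith-Waterman similarity sw(a,b)/sqrt(sw(a,a)*sw(b,b)).

    Raw local-alignment scores are unbounded; dividing by the geometric mean
    of the self-scores bounds the value to [0, 1] with self-similarity 1.
    Pass ``match``/``mismatch`` for a simple scoring scheme instead of a
    substitution matrix.
    """
    _validate_sequence(seq_a, "seq_a")
    _validate_sequence(seq_b, "seq_b")
    aligner = _make_aligner(matrix, gap_open, gap_extend, match, mismatch)
    raw = max(0.0, float(aligner.score(seq_a, seq_b)))
    self_a = float(aligner.score(seq_a, seq_a))
    self_b = float(aligner.score(seq_b, seq_b))
    return raw / np.sqrt(self_a * self_b)


# ---------------------------------------------------------------------------
# cross-pair aggregation
# ---------------------------------------------------------------------------

def target_pairwise_aggregate(targets_a, targets_b, pair_sim) -> tuple[float, float, float, float]:
    """(min, max, median, mean) of pair_sim over all |A| x |B| cross pairs.

    The median of an even count is the mean of the two central values
    (numpy convention).
    """
    ta, tb = sorted(targets_a), sorted(targets_b)
    if not ta or not tb:
        raise FeatureUnavailableError("empty effective target set")
    values = np.array([pair_sim(a, b) for a in ta for b in tb], dtype=float)
    vmin, vmax = float(values.min()), float(values.max())
    # clamp against 1-ulp drift so min <= med/mean <= max holds exactly
    med = float(np.clip(np.median(values), vmin, vmax))
    mean = float(np.clip(values.mean(), vmin, vmax))
    return (vmin, vmax, med, mean)


# ---------------------------------------------------------------------------
# GO semantic similarity (Wang)
# ---------------------------------------------------------------------------

def _wang_svalues(term: str, ontology: nx.DiGraph) -> dict[str, float]:
    """Semantic contributions of a term's ancestor closure (S-values).

    S(term) = 1; walking child->parent edges, S(parent) = max over in-paths of
    edge weight * S(child).  Memo-free DFS; ontologies here are small.
    """
    if term not in ontology:
        raise KeyError(f"unknown ontology term {term!r}")
    svals = {term: 1.0}
    stack = [term]
    while stack:
        node = stack.pop()
        for _, parent, data in ontology.out_edges(node, data=True):
            cand = data["weight"] * svals[node]
            if cand > svals.get(parent, 0.0):
                svals[parent] = cand
                stack.append(parent)
    return svals


def go_term_similarity(term_x: str, term_y: str, ontology: nx.DiGraph) -> float:
    """Wang graph-based semantic similarity of two ontology terms."""
    sx = _wang_svalues(term_x, ontology)
    sy = _wang_svalues(term_y, ontology)
    common = set(sx) & set(sy)
    if not common:
        return 0.0
    return sum(sx[t] + sy[t] for t in common) / (sum(sx.values()) + sum(sy.values()))


def go_bma_similarity(terms_x: frozenset[str], terms_y: frozenset[str],
                      ontology: nx.DiGraph,
                      term_sim_cache: dict[tuple[str, str], float] | None = None) -> float:
    """Best-match average of term similarities between two annotation sets."""
    tx, ty = sorted(terms_x), sorted(terms_y)
    if not tx or not ty:
        raise FeatureUnavailableError("target lacks GO annotation")

    def sim(a: str, b: str) -> float:
        if term_sim_cache is None:
            return go_term_similarity(a, b, ontology)
        key = (a, b) if a <= b else (b, a)
        if key not in term_sim_cache:
            term_sim_cache[key] = go_term_similarity(*key, ontology)
        return term_sim_cache[key]

    best_x = [max(sim(a, b) for b in ty) for a in tx]
    best_y = [max(sim(a, b) for a in tx) for b in ty]
    return (sum(best_x) + sum(best_y)) / (len(tx) + len(ty))


def go_gene_similarity(targets_a, targets_b, go_annotations, ontology,
                       term_sim_cache=None) -> tuple[float, float, float, float]:
    """Aggregated gene-level GO similarity over target cross pairs.

    Targets with no GO terms are dropped (logged); if either side loses all
    its targets the feature is unavailable for the pair.
    """
    eff_a = [t for t in sorted(targets_a) if go_annotations.get(t)]
    eff_b = [t for t in sorted(targets_b) if go_annotations.get(t)]
    dropped = (len(targets_a) - len(eff_a)) + (len(targets_b) - len(eff_b))
    if dropped:
        logger.debug("go: dropped %d unannotated target(s)", dropped)
    return target_pairwise_aggregate(
        eff_a, eff_b,
        lambda a, b: go_bma_similarity(go_annotations[a], go_annotations[b],
                                       ontology, term_sim_cache))


# ---------------------------------------------------------------------------
# pathway enrichment and similarity
# ---------------------------------------------------------------------------

@dataclass
class PathwayUniverse:
    """Ordered list of enriched pathways defining the pathway-vector axes."""

    pathway_ids: list[str]
    target_sets: dict[str, frozenset[str]]
    p_values: dict[str, float] = field(default_factory=dict)
    q_values: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathway_ids)


def enrich_pathways(all_targets: frozenset[str] | set[str],
                    pathways: dict[str, frozenset[str]],
                    background_size: int,
                    p_cutoff: float = 0.05, q_cutoff: float = 0.05) -> PathwayUniverse:
    """Hypergeometric over-representation screen defining the pathway universe.

    For each pathway with n members out of a background of M targets, the
    p-value is the upper tail P[X >= k] of Hypergeom(M, n, N) where N =
    |all_targets| drawn and k the observed overlap.  q-values are
    Benjamini-Hochberg; kept pathways satisfy p < p_cutoff and q < q_cutoff,
    in stable input order.
    """
    if background_size < len(all_targets):
        raise ValueError("background_size smaller than the drawn target set")
    all_targets = set(all_targets)
    if not all_targets:
        logger.warning("enrich_pathways: empty target set, empty pathway universe")
        return PathwayUniverse([], {})
    ids = list(pathways)
    pvals = np.array([
        stats.hypergeom.sf(len(all_targets & pathways[pid]) - 1,
                           background_size, len(pathways[pid]), len(all_targets))
        for pid in ids
    ])
    qvals = stats.false_discovery_control(pvals, method="bh")
    keep = [(pid, p, q) for pid, p, q in zip(ids, pvals, qvals)
            if p < p_cutoff and q < q_cutoff]
    logger.info("enrich_pathways: %d of %d pathways enriched (p<%.3g, q<%.3g)",
                len(keep), len(ids), p_cutoff, q_cutoff)
    return PathwayUniverse(
        pathway_ids=[pid for pid, _, _ in keep],
        target_sets={pid: pathways[pid] for pid, _, _ in keep},
        p_values={pid: float(p) for pid, p, _ in keep},
        q_values={pid: float(q) for pid, _, q in keep},
    )


def pathway_vector(target_set, universe: PathwayUniverse) -> np.ndarray:
    """Binary membership vector: bit k = 1 iff targets intersect pathway k."""
    targets = set(target_set)
    return np.array([int(bool(targets & universe.target_sets[pid]))
                     for pid in universe.pathway_ids], dtype=np.uint8)


def pathway_cosine(vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    """Cosine similarity of two pathway vectors; 0 if either vector is all-zero."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"pathway vector length mismatch: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b) / (na * nb)


# ---------------------------------------------------------------------------
# PPI distance features
# ---------------------------------------------------------------------------

def _sigma(d: float) -> float:
    return 1.0 / (1.0 + np.exp(-d))


def _graph_diameter(ppi: nx.Graph) -> int:
    """Max shortest-path distance over connected node pairs (any component)."""
    best = 0
    for comp in nx.connected_components(ppi):
        sub = ppi.subgraph(comp)
        if sub.number_of_nodes() > 1:
            best = max(best, nx.diameter(sub))
    return best


def ppi_features(targets_a, targets_b, ppi: nx.Graph,
                 config: RunConfig | None = None,
                 distance_cache: dict[str, dict[str, int]] | None = None,
                 diameter: int | None = None,
                 ) -> tuple[float, float, float, float, float]:
    """PPI shortest-path features and network proximity for a target-set pair.

    Returns (S_PPImin, S_PPImax, S_PPImed, S_PPImean, S_np).  Targets absent
    from the graph are dropped (logged); disconnected target pairs get
    d = diameter + 1 under the default policy or are dropped under
    ``drop-pair``.  ``S_PPImean`` uses sigma with the exponent sign set by
    ``config.ppi_sigmoid_sign`` ("as-printed": 1/(1+e^-d)).
    """
    config = config or RunConfig()
    in_a = [t for t in sorted(set(targets_a)) if t in ppi]
    in_b = [t for t in sorted(set(targets_b)) if t in ppi]
    if len(in_a) < len(set(targets_a)) or len(in_b) < len(set(targets_b)):
        logger.debug("ppi: dropped targets absent from the graph")
    if not in_a or not in_b:
        raise FeatureUnavailableError("no targets of one drug present in the PPI graph")

    if distance_cache is None:
        distance_cache = {}

    def dist_row(src: str) -> dict[str, int]:
        if src not in distance_cache:
            distance_cache[src] = dict(nx.single_source_shortest_path_length(ppi, src))
        return distance_cache[src]

    if diameter is None and config.disconnected_distance_policy == "diameter-plus-one":
        diameter = _graph_diameter(ppi)

    def cross_distances(sa: list[str], sb: list[str]):
        out: list[float] = []
        for a, b in itertools.product(sa, sb):
            row = dist_row(a)
            if b in row:
                out.append(float(row[b]))
            elif config.disconnected_distance_policy == "diameter-plus-one":
                out.append(float(diameter + 1))
            # drop-pair: omit
        return out

    between = cross_distances(in_a, in_b)
    if not between:
        raise FeatureUnavailableError(
            "all cross target pairs disconnected under drop-pair policy")

    def sigma_mean(dists: list[float]) -> float:
        mean_d = float(np.mean(dists))
        if config.ppi_sigmoid_sign == "inverted-mean":
            return 1.0 / (1.0 + np.exp(mean_d))
        return _sigma(mean_d)

    def within_sigma_mean(targets: list[str]) -> float:
        # full |A|^2 ordered-pair mean (diagonal zeros included), the same
        # mean formula as the between-set term, so S_np(A, A) = 0 exactly
        # and a singleton baseline is sigma(0) = 0.5
        dists = cross_distances(targets, targets)
        if not dists:
            dists = [0.0]
        return sigma_mean(dists)

    s_min = _sigma(min(between))
    s_max = _sigma(max(between))
    s_med = _sigma(float(np.median(between)))
    s_mean = sigma_mean(between)
    s_np = s_mean - (within_sigma_mean(in_a) + within_sigma_mean(in_b)) / 2.0
    return s_min, s_max, s_med, s_mean, s_np


# ---------------------------------------------------------------------------
# full pair featurization
# ---------------------------------------------------------------------------

class UniverseFeaturizer:
    """Featurize drug pairs of one universe with cached target-level matrices.

    Precomputes, lazily and per target pair, the normalized Smith-Waterman
    similarity, the gene-level GO BMA similarity and the PPI shortest-path
    rows, then assembles the 16-component feature vector per drug pair.
    """

    def __init__(self, drugs: list[DrugRecord], context: TargetContext,
                 config: RunConfig | None = None,
                 pathway_universe: PathwayUniverse | None = None,
                 background_size: int | None = None):
        self.config = config or RunConfig()
        self.context = context
        self.drugs = {d.drug_id: d for d in drugs}
        if len(self.drugs) != len(drugs):
            raise ValueError("duplicate drug_id in universe")
        self.normalizer = AdmeNormalizer.from_universe(drugs)
        if pathway_universe is None:
            all_targets = frozenset().union(*(d.target_ids for d in drugs)) \
                if drugs else frozenset()
            bg = background_size or len(context.all_targets())
            pathway_universe = enrich_pathways(all_targets, context.pathways, bg)
        self.pathway_universe = pathway_universe
        self._seq_cache: dict[tuple[str, str], float] = {}
        self._go_cache: dict[tuple[str, str], float] = {}
        self._go_term_cache: dict[tuple[str, str], float] = {}
        self._ppi_dist_cache: dict[str, dict[str, int]] = {}
        self._pathway_vec_cache: dict[str, np.ndarray] = {}
        self._diameter = (_graph_diameter(context.ppi)
                          if self.config.disconnected_distance_policy == "diameter-plus-one"
                          else None)

    # -- cached elementary similarities ------------------------------------

    def _seq_sim(self, ta: str, tb: str) -> float:
        key = (ta, tb) if ta <= tb else (tb, ta)
        if key not in self._seq_cache:
            self._seq_cache[key] = sw_similarity(
                self.context.sequences[key[0]], self.context.sequences[key[1]])
        return self._seq_cache[key]

    def _go_sim(self, ta: str, tb: str) -> float:
        key = (ta, tb) if ta <= tb else (tb, ta)
        if key not in self._go_cache:
            self._go_cache[key] = go_bma_similarity(
                self.context.go_annotations[key[0]],
                self.context.go_annotations[key[1]],
                self.context.ontology, self._go_term_cache)
        return self._go_cache[key]

    def _pathway_vec(self, drug: DrugRecord) -> np.ndarray:
        if drug.drug_id not in self._pathway_vec_cache:
            self._pathway_vec_cache[drug.drug_id] = pathway_vector(
                drug.target_ids, self.pathway_universe)
        return self._pathway_vec_cache[drug.drug_id]

    # -- assembly -----------------------------------------------------------

    def featurize_pair(self, drug_a: str | DrugRecord, drug_b: str | DrugRecord) -> dict[str, float]:
        """The 16 named features for one unordered drug pair."""
        da = self.drugs[drug_a] if isinstance(drug_a, str) else drug_a
        db = self.drugs[drug_b] if isinstance(drug_b, str) else drug_b
        if not da.target_ids or not db.target_ids:
            raise FeatureUnavailableError(
                f"pair ({da.drug_id}, {db.drug_id}): a drug has no targets")
        feats: dict[str, float] = {}
        try:
            feats["S_FP"] = tanimoto_fingerprint(da.fingerprint, db.fingerprint)
            feats["S_ADME"] = adme_distance(da.adme, db.adme, self.normalizer)

            seq_a = [t for t in da.target_ids if t in self.context.sequences]
            seq_b = [t for t in db.target_ids if t in self.context.sequences]
            (feats["S_Seqmin"], feats["S_Seqmax"],
             feats["S_Seqmed"], feats["S_Seqmean"]) = target_pairwise_aggregate(
                seq_a, seq_b, self._seq_sim)

            go_a = [t for t in da.target_ids if self.context.go_annotations.get(t)]
            go_b = [t for t in db.target_ids if self.context.go_annotations.get(t)]
            (feats["S_GOmin"], feats["S_GOmax"],
             feats["S_GOmed"], feats["S_GOmean"]) = target_pairwise_aggregate(
                go_a, go_b, self._go_sim)

            feats["S_Pathway"] = pathway_cosine(self._pathway_vec(da),
                                                self._pathway_vec(db))

            (feats["S_PPImin"], feats["S_PPImax"], feats["S_PPImed"],
             feats["S_PPImean"], feats["S_np"]) = ppi_features(
                da.target_ids, db.target_ids, self.context.ppi, self.config,
                distance_cache=self._ppi_dist_cache, diameter=self._diameter)
        except (FeatureUnavailableError, DegenerateInputError) as exc:
            raise FeatureUnavailableError(
                f"pair ({da.drug_id}, {db.drug_id}): {exc}") from exc
        return feats

    def featurize_pairs(self, pairs, labels: dict[tuple[str, str], bool] | None = None,
                        ) -> pd.DataFrame:
        """Feature table for many pairs, indexed by canonical pair tuples."""
        rows, index = [], []
        for pair in pairs:
            a, b = (pair.drug_a, pair.drug_b) if hasattr(pair, "drug_a") else pair
            key = canonical_pair(a, b)
            feats = self.featurize_pair(*key)
            label: float | bool
            if labels is not None:
                label = labels.get(key, np.nan)
            elif hasattr(pair, "label"):
                label = pair.label
            else:
                label = np.nan
            rows.append({"label": label, **feats})
            index.append(key)
        df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
            index, names=["drug_a", "drug_b"]))
        return df[["label", *FEATURE_NAMES]]


def featurize_pair(drug_a: DrugRecord, drug_b: DrugRecord, context: TargetContext,
                   universe: PathwayUniverse, normalizer: AdmeNormalizer,
                   config: RunConfig | None = None) -> dict[str, float]:
    """One-shot pair featurization (convenience over UniverseFeaturizer)."""
    uniq = [drug_a] if drug_a.drug_id == drug_b.drug_id else [drug_a, drug_b]
    feat = UniverseFeaturizer(uniq, context, config, pathway_universe=universe)
    feat.normalizer = normalizer
    return feat.featurize_pair(drug_a.drug_id, drug_b.drug_id)
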