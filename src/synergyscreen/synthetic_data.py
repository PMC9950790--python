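"""Synthetic drug universe and dose-response generator with known ground truth.

Every pipeline stage is testable offline: the generator emulates the
statistical structure of the real inputs (sparse binary fingerprints,
correlated ADME descriptors, random protein sequences, a small GO DAG with
per-target annotations, pathway target sets, a preferential-attachment PPI
graph) and plants a recoverable combination signal — pair labels drawn from
a logistic model on true pair features (by default positive weight on
S_Pathway and S_np) — so that classifier and feature-screen recovery are
meaningful checks.  Dose-response curves come from the median-effect model
itself, with known (m, Dm) and, for combinations, known CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .io_core import (
    AMINO_ACIDS,
    DrugRecord,
    TargetContext,
    canonical_pair,
    derive_seed,
    write_drug_table,
    write_gmt,
    write_ontology_tsv,
    write_ppi,
)
from .synergy_ci import DoseResponse, MedianEffectFit, dose_for_effect

logger = logging.getLogger("synergyscreen")


@dataclass
class UniverseSpec:
    """Scale and shape of one synthetic drug universe.

    Defaults are a desk-scale universe (20 drugs, 60 targets, 200-node PPI)
    that runs the whole pipeline in minutes while keeping every feature
    family non-degenerate.
    """

    n_drugs: int = 20
    fingerprint_len: int = 1024
    fingerprint_density: float = 0.2
    adme_dim: int = 12
    adme_ranges: tuple[float, float] = (0.0, 500.0)
    n_targets: int = 60
    seq_len_range: tuple[int, int] = (80, 200)
    n_go_terms: int = 40
    go_terms_per_target: tuple[int, int] = (2, 6)
    n_pathways: int = 15
    pathway_size_range: tuple[int, int] = (4, 12)
    ppi_nodes: int = 200
    ppi_attach_edges: int = 2  # preferential-attachment m
    targets_per_drug: tuple[int, int] = (3, 8)
    pathway_focus_prob: float = 0.5  # fraction of drugs drawing targets from one pathway
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1:
            raise ValueError("n_drugs must be >= 1")
        for name in ("fingerprint_len", "adme_dim", "n_targets", "n_go_terms",
                     "n_pathways", "ppi_nodes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.fingerprint_density < 1.0:
            raise ValueError("fingerprint_density must lie in (0, 1)")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_universe(spec: UniverseSpec) -> tuple[list[DrugRecord], TargetContext]:
    """Reproducible toy universe: drugs + shared target context."""
    rng = np.random.default_rng(spec.seed)
    target_ids = [f"T{i:04d}" for i in range(spec.n_targets)]

    sequences = {t: _random_sequence(rng, int(rng.integers(*spec.seq_len_range)))
                 for t in target_ids}

    # GO DAG: random tree (each non-root term attaches to an earlier term)
    # plus a few shortcut edges; 80/20 is_a vs part_of.
    terms = [f"GO:{i:07d}" for i in range(spec.n_go_terms)]
    ontology = nx.DiGraph()
    ontology.add_nodes_from(terms)
    for i in range(1, spec.n_go_terms):
        parent = terms[int(rng.integers(0, i))]
        rel = "is_a" if rng.random() < 0.8 else "part_of"
        ontology.add_edge(terms[i], parent, relation=rel,
                          weight=0.8 if rel == "is_a" else 0.6)
    for _ in range(spec.n_go_terms // 5):
        i = int(rng.integers(2, spec.n_go_terms))
        j = int(rng.integers(0, i))
        if not ontology.has_edge(terms[i], terms[j]):
            ontology.add_edge(terms[i], terms[j], relation="part_of", weight=0.6)

    lo, hi = spec.go_terms_per_target
    go_annotations = {
        t: frozenset(rng.choice(terms, size=int(rng.integers(lo, hi + 1)),
                                replace=False).tolist())
        for t in target_ids}

    plo, phi = spec.pathway_size_range
    pathways = {
        f"PW{i:03d}": frozenset(rng.choice(target_ids,
                                           size=int(rng.integers(plo, phi + 1)),
                                           replace=False).tolist())
        for i in range(spec.n_pathways)}

    # PPI: Barabasi-Albert graph; targets occupy a random subset of nodes.
    ba = nx.barabasi_albert_graph(spec.ppi_nodes, spec.ppi_attach_edges,
                                  seed=int(rng.integers(2**31)))
    node_names = [f"P{i:04d}" for i in range(spec.ppi_nodes)]
    target_slots = rng.choice(spec.ppi_nodes, size=spec.n_targets, replace=False)
    for slot, t in zip(target_slots, target_ids):
        node_names[slot] = t
    ppi = nx.relabel_nodes(ba, dict(enumerate(node_names)))

    context = TargetContext(sequences=sequences, go_annotations=go_annotations,
                            ontology=ontology, pathways=pathways, ppi=ppi)

    pathway_list = list(pathways)
    tlo, thi = spec.targets_per_drug
    drugs: list[DrugRecord] = []
    # correlated ADME slots: one latent severity factor per drug
    slot_loadings = rng.uniform(0.3, 1.0, size=spec.adme_dim)
    alo, ahi = spec.adme_ranges
    for i in range(spec.n_drugs):
        fingerprint = (rng.random(spec.fingerprint_len)
                       < spec.fingerprint_density).astype(np.uint8)
        if not fingerprint.any():
            fingerprint[int(rng.integers(spec.fingerprint_len))] = 1
        latent = rng.normal()
        adme = alo + (ahi - alo) * expit(slot_loadings * latent
                                         + rng.normal(scale=0.5, size=spec.adme_dim))
        n_t = int(rng.integers(tlo, thi + 1))
        if rng.random() < spec.pathway_focus_prob:
            # pathway-focused drug: most targets from one pathway
            pw = sorted(pathways[pathway_list[int(rng.integers(spec.n_pathways))]])
            k = min(n_t, len(pw))
            targets = set(rng.choice(pw, size=k, replace=False).tolist())
            while len(targets) < n_t:
                targets.add(target_ids[int(rng.integers(spec.n_targets))])
        else:
            targets = set(rng.choice(target_ids, size=n_t, replace=False).tolist())
        drugs.append(DrugRecord(drug_id=f"D{i:03d}", display_name=f"drug-{i:03d}",
                                fingerprint=fingerprint, adme=adme,
                                target_ids=frozenset(targets)))
    logger.info("generate_universe: %d drugs, %d targets, PPI %d/%d, seed %d",
                spec.n_drugs, spec.n_targets, ppi.number_of_nodes(),
                ppi.number_of_edges(), spec.seed)
    return drugs, context


def write_universe(drugs: list[DrugRecord], context: TargetContext,
                   directory: str | Path) -> dict[str, Path]:
    """Serialize a universe into the files the io_core readers accept."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "drug_table": directory / "drugs.tsv",
        "fasta": directory / "targets.fasta",
        "go_gmt": directory / "go_annotations.gmt",
        "ontology": directory / "ontology.tsv",
        "pathway_gmt": directory / "pathways.gmt",
        "ppi": directory / "ppi_edges.tsv",
    }
    write_drug_table(drugs, paths["drug_table"])
    with open(paths["fasta"], "w") as fh:
        for t, seq in sorted(context.sequences.items()):
            fh.write(f">{t}\n{seq}\n")
    term_to_targets: dict[str, set[str]] = {}
    for t, terms in context.go_annotations.items():
        for term in terms:
            term_to_targets.setdefault(term, set()).add(t)
    write_gmt(term_to_targets, paths["go_gmt"])
    write_ontology_tsv(context.ontology, paths["ontology"])
    write_gmt(context.pathways, paths["pathway_gmt"])
    write_ppi(context.ppi, paths["ppi"])
    return paths


# ---------------------------------------------------------------------------
# planted labels
# ---------------------------------------------------------------------------

@dataclass
class PlantedLabelModel:
    """Logistic label model on (z-scored) pair-feature columns.

    The default plants the combination signal on S_Pathway with a secondary
    weight on S_np, so the screen's own key variables are recoverable.  The
    intercept is calibrated so the marginal positive rate matches
    ``base_rate``.
    """

    coefficients: dict[str, float] = field(
        default_factory=lambda: {"S_Pathway": 4.0, "S_np": 2.0})
    base_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate < 1.0:
            raise ValueError("base_rate must lie in [0, 1)")


def plant_labels(features: pd.DataFrame, model: PlantedLabelModel,
                 ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Label each pair positive with probability logistic(b0 + beta . z).

    z are the z-scored feature columns named in ``model.coefficients``
    (constant columns contribute 0).  Returns disjoint positive and negative
    pair-key lists in the input order.
    """
    if model.base_rate == 0.0:
        return [], [canonical_pair(*key) for key in features.index]
    eta = np.zeros(len(features))
    for name, beta in model.coefficients.items():
        col = features[name].to_numpy(dtype=float)
        sd = col.std()
        if sd > 0:
            eta += beta * (col - col.mean()) / sd

    def mean_rate(b0: float) -> float:
        return float(expit(b0 + eta).mean())

    b0 = optimize.brentq(lambda b: mean_rate(b) - model.base_rate, -50, 50)
    rng = np.random.default_rng(model.seed)
    draws = rng.random(len(features))
    positives, negatives = [], []
    for key, p, u in zip(features.index, expit(b0 + eta), draws):
        (positives if u < p else negatives).append(canonical_pair(*key))
    logger.info("plant_labels: %d positives / %d negatives (target rate %.3f)",
                len(positives), len(negatives), model.base_rate)
    return positives, negatives


# ---------------------------------------------------------------------------
# dose-response simulation
# ---------------------------------------------------------------------------

def median_effect_fa(dose: np.ndarray | float, m: float, dm: float):
    """fa = 1 / (1 + (dm/D)^m), the median-effect dose-response curve."""
    dose = np.asarray(dose, dtype=float)
    return 1.0 / (1.0 + (dm / dose) ** m)


def simulate_dose_response(m: float, dm: float, doses, noise_sd: float,
                           seed: int, agent_id: str = "agent") -> DoseResponse:
    """Median-effect curve with multiplicative log-normal noise on fa."""
    if m <= 0 or dm <= 0:
        raise ValueError("m and dm must be positive")
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be strictly positive")
    fa = median_effect_fa(doses, m, dm)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fa = fa * np.exp(rng.normal(scale=noise_sd, size=fa.shape))
    return DoseResponse(agent_id=agent_id, doses=doses, fa=np.clip(fa, 0.0, 1.0))


def simulate_combination(fit_a: MedianEffectFit, fit_b: MedianEffectFit,
                         dose_grid: list[tuple[float, float]],
                         mode: str = "loewe_additive",
                         ci_value: float | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Combination rows whose true CI is known by construction.

    ``loewe_additive`` solves fa so d_a/(D_A)_x + d_b/(D_B)_x = 1 on each
    grid row; ``fixed_ci`` solves for an arbitrary target CI > 0.  Rows whose
    dose pair cannot reach the target CI inside fa in (eps, 1-eps) are
    flagged ``achievable = False`` and carry NaN fa.
    """
    if mode == "loewe_additive":
        target = 1.0
    elif mode == "fixed_ci":
        if ci_value is None or ci_value <= 0:
            raise ValueError("fixed_ci mode requires ci_value > 0")
        target = float(ci_value)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    eps = 1e-9
    rows = []
    for d_a, d_b in dose_grid:
        def ci_at(fa: float) -> float:
            return (d_a / dose_for_effect(fit_a, fa)
                    + d_b / dose_for_effect(fit_b, fa))

        lo_v, hi_v = ci_at(1 - eps), ci_at(eps)  # CI decreasing in fa
        if not (lo_v <= target <= hi_v):
            logger.warning("simulate_combination: dose pair (%g, %g) cannot "
                           "reach CI %g; skipped", d_a, d_b, target)
            rows.append({"agent_a": fit_a.agent_id, "agent_b": fit_b.agent_id,
                         "dose_a": d_a, "dose_b": d_b, "fa": np.nan,
                         "achievable": False})
            continue
        fa = optimize.brentq(lambda f: ci_at(f) - target, eps, 1 - eps,
                             xtol=1e-12, rtol=1e-12)
        rows.append({"agent_a": fit_a.agent_id, "agent_b": fit_b.agent_id,
                     "dose_a": d_a, "dose_b": d_b, "fa": float(fa),
                     "achievable": True})
    return pd.DataFrame(rows)
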