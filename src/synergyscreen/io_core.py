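"""Shared data model, file formats, configuration and seeding.

The drug universe consists of per-drug binary molecular fingerprints, ADME
descriptor vectors and protein-target sets, plus a target context shared by
all drugs: amino-acid sequences, GO annotations over an ontology DAG,
pathway membership sets, and an undirected protein-protein interaction (PPI)
graph.  Everything downstream (pair featurization, screening, ensemble
training, voting, synergy evaluation) consumes these containers.

File formats are deliberately plain: TSV drug table, FASTA sequences, GMT
set files for pathways and GO annotations, OBO or 3-column TSV ontology,
2-column TSV PPI edge list, CSV dose-response tables, YAML run config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("synergyscreen")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed column order of the 16 pair features in every feature table.
FEATURE_NAMES = [
    "S_FP", "S_ADME",
    "S_Seqmin", "S_Seqmax", "S_Seqmed", "S_Seqmean",
    "S_GOmin", "S_GOmax", "S_GOmed", "S_GOmean",
    "S_Pathway",
    "S_PPImin", "S_PPImax", "S_PPImed", "S_PPImean",
    "S_np",
]

#: Semantic-contribution weight of each ontology edge type (Wang method).
ONTOLOGY_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class FormatError(ValueError):
    """Malformed input file (bad bit-string, duplicate id, cyclic ontology...)."""


class DegenerateInputError(ValueError):
    """Mathematically undefined input (e.g. all-zero fingerprint)."""


class FeatureUnavailableError(ValueError):
    """A pair feature cannot be computed (e.g. no annotated targets)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DrugRecord:
    """One small molecule: fingerprint bits, ADME vector, target-id set."""

    drug_id: str
    display_name: str
    fingerprint: np.ndarray  # binary, length F (default 1024)
    adme: np.ndarray         # real, length K (default 12), raw units
    target_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.fingerprint = np.asarray(self.fingerprint, dtype=np.uint8)
        if not np.isin(self.fingerprint, (0, 1)).all():
            raise FormatError(f"drug {self.drug_id}: fingerprint entries must be 0/1")
        self.adme = np.asarray(self.adme, dtype=float)
        self.target_ids = frozenset(self.target_ids)


@dataclass
class TargetContext:
    """Target-level annotation shared across the whole drug universe."""

    sequences: dict[str, str]
    go_annotations: dict[str, frozenset[str]]
    ontology: nx.DiGraph              # edges child -> parent, attrs relation/weight
    pathways: dict[str, frozenset[str]]
    ppi: nx.Graph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.ontology):
            raise FormatError("ontology graph is cyclic")
        if any(self.ppi.has_edge(n, n) for n in self.ppi):
            raise FormatError("PPI graph contains self-loops")
        for pid, members in self.pathways.items():
            if not members:
                raise FormatError(f"pathway {pid} is empty")

    def all_targets(self) -> frozenset[str]:
        ids: set[str] = set(self.sequences)
        ids.update(self.go_annotations)
        for members in self.pathways.values():
            ids.update(members)
        ids.update(self.ppi.nodes)
        return frozenset(ids)


def canonical_pair(drug_a: str, drug_b: str) -> tuple[str, str]:
    """Unordered-pair identity: (a, b) and (b, a) map to one sorted tuple."""
    if drug_a == drug_b:
        raise ValueError(f"pair of a drug with itself: {drug_a}")
    return (drug_a, drug_b) if drug_a < drug_b else (drug_b, drug_a)


@dataclass(frozen=True)
class LabeledPair:
    """An unordered drug pair with a combination (positive) / non-combination label."""

    drug_a: str
    drug_b: str
    label: bool  # True = combination

    def __post_init__(self) -> None:
        a, b = canonical_pair(self.drug_a, self.drug_b)
        object.__setattr__(self, "drug_a", a)
        object.__setattr__(self, "drug_b", b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)


@dataclass
class RunConfig:
    """Tunable knobs of the whole screen; all randomness flows from master_seed."""

    ratio_neg_per_pos: int = 5
    n_resamples: int = 1000
    cv_folds: int = 10
    cv_repeats: int = 3
    feature_frequency_cutoff: float = 0.70
    vote_select_threshold: int = 700
    rf_ntree: int = 300
    master_seed: int = 0
    ppi_sigmoid_sign: str = "as-printed"       # or "inverted-mean"
    disconnected_distance_policy: str = "diameter-plus-one"  # or "drop-pair"
    # screening-stage knobs (inner RFE); recorded so the run is reproducible
    rfe_ntree: int = 50
    rfe_cv_folds: int = 5
    eval_mode: str = "cv"                      # or "holdout" (70/30 internal validation)

    def __post_init__(self) -> None:
        for name in ("ratio_neg_per_pos", "n_resamples", "cv_folds", "cv_repeats",
                     "rf_ntree", "rfe_ntree", "rfe_cv_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.feature_frequency_cutoff <= 1.0:
            raise ValueError("feature_frequency_cutoff must lie in (0, 1]")
        if self.ppi_sigmoid_sign not in ("as-printed", "inverted-mean"):
            raise ValueError(f"unknown ppi_sigmoid_sign {self.ppi_sigmoid_sign!r}")
        if self.disconnected_distance_policy not in ("diameter-plus-one", "drop-pair"):
            raise ValueError(
                f"unknown disconnected_distance_policy {self.disconnected_distance_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
        return path


def derive_seed(master_seed: int, stage: str, index: int | None = None) -> int:
    """Per-stage seed derivation: stage name hashed with the master seed.

    Any single stage (or single resample, via ``index``) is reproducible in
    isolation.  Result is always < 2**31.
    """
    token = f"{master_seed}:{stage}" + ("" if index is None else f":{index}")
    digest = hashlib.sha256(token.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """GMT set-per-line: name <TAB> description <TAB> member1 <TAB> member2 ..."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, members")
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
    return path


def read_ontology(path: str | Path) -> nx.DiGraph:
    """Ontology DAG from OBO (via obonet) or 3-column TSV (child, parent, relation).

    Edges run child -> parent and carry ``relation`` and Wang semantic-
    contribution ``weight`` attributes.
    """
    path = Path(path)
    graph = nx.DiGraph()
    if path.suffix == ".obo":
        import obonet

        obo = obonet.read_obo(path)
        graph.add_nodes_from(obo.nodes)
        for child, parent, rel in obo.edges(keys=True):
            weight = ONTOLOGY_EDGE_WEIGHTS.get(rel, ONTOLOGY_EDGE_WEIGHTS["part_of"])
            graph.add_edge(child, parent, relation=rel, weight=weight)
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise FormatError(f"{path}:{lineno}: ontology TSV needs child, parent, relation")
                child, parent, rel = parts
                if rel not in ONTOLOGY_EDGE_WEIGHTS:
                    raise FormatError(f"{path}:{lineno}: unknown relation {rel!r}")
                graph.add_node(child)
                graph.add_node(parent)
                graph.add_edge(child, parent, relation=rel,
                               weight=ONTOLOGY_EDGE_WEIGHTS[rel])
    if not nx.is_directed_acyclic_graph(graph):
        raise FormatError(f"{path}: ontology graph is cyclic")
    return graph


def write_ontology_tsv(ontology: nx.DiGraph, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for child, parent, data in sorted(ontology.edges(data=True)):
            fh.write(f"{child}\t{parent}\t{data['relation']}\n")
    return path


def read_ppi(path: str | Path) -> nx.Graph:
    """Undirected PPI edge list (2-column TSV); self-loops and duplicate edges dropped."""
    graph = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: PPI edge needs two columns")
            a, b = parts[0], parts[1]
            if a == b:
                n_self += 1
                continue
            graph.add_edge(a, b)
    if n_self:
        logger.warning("ppi: dropped %d self-loop rows from %s", n_self, path)
    return graph


def write_ppi(graph: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")
    return path


def read_drug_table(path: str | Path) -> list[DrugRecord]:
    """TSV with header drug_id, name, fingerprint, adme_1..adme_K, targets.

    The fingerprint is a 0/1 string; targets are semicolon-separated ids
    (empty allowed at load time — such drugs are rejected only at
    featurization).  K is inferred from the header.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"drug_id", "name", "fingerprint", "targets"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    adme_cols = [c for c in df.columns if c.startswith("adme_")]
    adme_cols.sort(key=lambda c: int(c.split("_", 1)[1]))
    records: list[DrugRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        drug_id = row.drug_id
        if drug_id in seen:
            raise FormatError(f"{path}: duplicate drug_id {drug_id!r}")
        seen.add(drug_id)
        bits = row.fingerprint
        if set(bits) - {"0", "1"}:
            raise FormatError(
                f"{path}: drug {drug_id!r}: fingerprint contains non-0/1 characters")
        fingerprint = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
        try:
            adme = np.array([float(getattr(row, c)) for c in adme_cols])
        except ValueError as exc:
            raise FormatError(f"{path}: drug {drug_id!r}: bad ADME value ({exc})") from exc
        targets = frozenset(t for t in row.targets.split(";") if t)
        records.append(DrugRecord(drug_id, row.name, fingerprint, adme, targets))
    return records


def write_drug_table(drugs: Iterable[DrugRecord], path: str | Path) -> Path:
    drugs = list(drugs)
    path = Path(path)
    k = len(drugs[0].adme) if drugs else 0
    cols = ["drug_id", "name", "fingerprint", *[f"adme_{i+1}" for i in range(k)], "targets"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for d in drugs:
            row = [d.drug_id, d.display_name,
                   "".join(map(str, d.fingerprint.tolist())),
                   *[f"{v:.17g}" for v in d.adme],
                   ";".join(sorted(d.target_ids))]
            fh.write("\t".join(row) + "\n")
    return path


def read_universe(drug_table_path: str | Path, fasta_path: str | Path,
                  go_gmt_path: str | Path, ontology_path: str | Path,
                  pathway_gmt_path: str | Path, ppi_edge_path: str | Path,
                  ) -> tuple[list[DrugRecord], TargetContext]:
    """Load and validate the full drug universe from its six files.

    Targets referenced by a drug but lacking a sequence are logged and
    retained; they are excluded only from sequence-based features downstream.
    """
    drugs = read_drug_table(drug_table_path)
    sequences = {rec.id: str(rec.seq).upper()
                 for rec in SeqIO.parse(str(fasta_path), "fasta")}
    go_sets = read_gmt(go_gmt_path)  # term -> targets; inverted below
    go_annotations: dict[str, set[str]] = {}
    for term, targets in go_sets.items():
        for t in targets:
            go_annotations.setdefault(t, set()).add(term)
    ontology = read_ontology(ontology_path)
    pathways = read_gmt(pathway_gmt_path)
    ppi = read_ppi(ppi_edge_path)
    context = TargetContext(
        sequences=sequences,
        go_annotations={t: frozenset(v) for t, v in go_annotations.items()},
        ontology=ontology,
        pathways=pathways,
        ppi=ppi,
    )
    n_missing = sum(1 for d in drugs for t in d.target_ids if t not in sequences)
    if n_missing:
        logger.warning("universe: %d drug-target references lack a sequence "
                       "(kept; excluded from sequence features)", n_missing)
    logger.info("universe: %d drugs, %d sequences, %d pathways, PPI %d nodes / %d edges",
                len(drugs), len(sequences), len(pathways),
                ppi.number_of_nodes(), ppi.number_of_edges())
    return drugs, context


# ---------------------------------------------------------------------------
# pair and feature tables
# ---------------------------------------------------------------------------

def read_pair_table(path: str | Path) -> list[LabeledPair]:
    """TSV with columns drug_a, drug_b and optional label (1/0/NA)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    pairs: list[LabeledPair] = []
    for row in df.itertuples(index=False):
        label = getattr(row, "label", "NA")
        pairs.append(LabeledPair(row.drug_a, row.drug_b,
                                 label not in ("0", "NA", "", None)))
    return pairs


def write_pair_table(pairs: Iterable[LabeledPair], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("drug_a\tdrug_b\tlabel\n")
        for p in pairs:
            fh.write(f"{p.drug_a}\t{p.drug_b}\t{int(p.label)}\n")
    return path


def write_feature_table(features: pd.DataFrame, path: str | Path) -> Path:
    """Write a pair-feature table: drug_a, drug_b, label, then the 16 features.

    ``features`` is indexed by canonical (drug_a, drug_b) tuples with a
    ``label`` column (NA allowed for candidates) and the FEATURE_NAMES
    columns.  Values round-trip to 12 significant digits.
    """
    path = Path(path)
    if missing := [c for c in FEATURE_NAMES if c not in features.columns]:
        raise FormatError(f"feature table missing columns {missing}")
    if features[FEATURE_NAMES].isna().any().any():
        bad = features.index[features[FEATURE_NAMES].isna().any(axis=1)].tolist()
        raise FormatError(f"missing feature values for pairs {bad}")
    with open(path, "w") as fh:
        fh.write("\t".join(["drug_a", "drug_b", "label", *FEATURE_NAMES]) + "\n")
        for (a, b), row in features.iterrows():
            label = row.get("label")
            label_s = "NA" if label is None or (isinstance(label, float) and np.isnan(label)) \
                else str(int(label))
            vals = [f"{row[c]:.12g}" for c in FEATURE_NAMES]
            fh.write("\t".join([a, b, label_s, *vals]) + "\n")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df.index = pd.MultiIndex.from_arrays(
        [df.pop("drug_a"), df.pop("drug_b")], names=["drug_a", "drug_b"])
    return df


# ---------------------------------------------------------------------------
# dose-response CSV
# ---------------------------------------------------------------------------

def read_dose_response(path: str | Path) -> pd.DataFrame:
    """Single-agent dose-response CSV: agent_id, dose (umol/L), fa (0..1)."""
    df = pd.read_csv(path)
    if missing := {"agent_id", "dose", "fa"} - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_dose_response(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_combination_table(path: str | Path) -> pd.DataFrame:
    """Combination observations CSV: agent_a, agent_b, dose_a, dose_b, fa."""
    df = pd.read_csv(path)
    if missing := {"agent_a", "agent_b", "dose_a", "dose_b", "fa"} - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
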