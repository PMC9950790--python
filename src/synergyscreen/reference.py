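"""Reference values reported by the original combination screen.

These printed numbers are inputs to self-consistency checks (e.g. that the
reported F1 scores follow from the reported precision and recall, or that
the per-pair minimum combination index separates the synergistic pairs);
they are never targets the pipeline is fitted toward.
"""

from __future__ import annotations

#: Positive (combination) training pairs and the negative pool of the
#: original screen, and the resampling protocol applied to them.
N_POSITIVE_PAIRS = 404
N_NEGATIVE_POOL = 45603
NEG_PER_POS_RATIO = 5
N_RESAMPLES = 1000

#: Candidate enumeration: TCM ingredient small molecules x Western anti-RA drugs.
N_TCM_DRUGS = 41
N_WESTERN_DRUGS = 10

#: Vote-count bin sizes over the 410 candidates (>500, 100-500, 1-100, 0 votes).
VOTE_BIN_COUNTS = {"gt500": 34, "100to500": 62, "1to100": 114, "zero": 200}
VOTE_SELECT_THRESHOLD = 700
N_SELECTED_PAIRS = 15

#: Reported mean cross-validated metrics per classifier (accuracy, precision,
#: recall, F1, AUROC, AUPRC).
MODEL_METRICS = {
    "knn":      {"accuracy": 0.827, "precision": 0.848, "recall": 0.965,
                 "f1": 0.903, "auroc": 0.651, "auprc": 0.309},
    "nb":       {"accuracy": 0.813, "precision": 0.845, "recall": 0.949,
                 "f1": 0.894, "auroc": 0.617, "auprc": 0.269},
    "svm_rbf":  {"accuracy": 0.834, "precision": 0.838, "recall": 0.992,
                 "f1": 0.909, "auroc": 0.657, "auprc": 0.330},
    "rf":       {"accuracy": 0.849, "precision": 0.861, "recall": 0.977,
                 "f1": 0.915, "auroc": 0.739, "auprc": 0.460},
    "adaboost": {"accuracy": 0.833, "precision": 0.834, "recall": 0.998,
                 "f1": 0.909, "auroc": 0.667, "auprc": 0.317},
}

#: The 15 highest-vote candidate pairs (TCM ingredient, Western drug, votes).
TOP_VOTED_PAIRS = [
    ("Eugenol", "Acetaminophen", 993),
    ("(-)-Epicatechin", "Celecoxib", 957),
    ("Rosmarinic acid", "Celecoxib", 946),
    ("Chenodeoxycholic acid", "Acetaminophen", 929),
    ("Eugenol", "Diclofenac", 912),
    ("Eugenol", "Naproxen", 910),
    ("Myricetin", "Celecoxib", 908),
    ("Chenodeoxycholic acid", "Diclofenac", 898),
    ("Chenodeoxycholic acid", "Naproxen", 897),
    ("Rhein", "Celecoxib", 894),
    ("Anethole", "Naproxen", 854),
    ("Anethole", "Diclofenac", 853),
    ("Nobiletin", "Celecoxib", 832),
    ("Fisetin", "Celecoxib", 791),
    ("Rhein", "Hydroxychloroquine", 770),
]

#: Per-row combination-index observations of the seven experimentally tested
#: pairs: (dose of the TCM ingredient, dose of the Western drug, CI).  The two
#: antagonistic pairs printed no per-dose rows, only "CI > 1"; they are
#: encoded with an empty row list and pair-level minimum CI above 1.
CI_OBSERVATIONS = {
    ("Rhein", "Celecoxib"): [
        (100, 100, 0.37), (20, 100, 0.49), (4, 100, 0.39),
        (100, 20, 0.40), (100, 4, 0.17), (20, 20, 0.40),
    ],
    ("Nobiletin", "Celecoxib"): [(100, 100, 0.01), (100, 20, 0.17)],
    ("Myricetin", "Celecoxib"): [
        (100, 100, 0.06), (20, 100, 0.46), (4, 100, 0.41),
        (100, 20, 0.03), (100, 4, 0.02),
    ],
    ("Fisetin", "Celecoxib"): [(100, 100, 0.02), (4, 100, 0.88)],
    ("Rhein", "Hydroxychloroquine"): [(100, 20, 0.28)],
    ("(-)-Epicatechin", "Celecoxib"): [],
    ("Rosmarinic acid", "Celecoxib"): [],
}

#: Pair-level minimum CI; pairs with no per-dose rows were reported only as
#: antagonistic (CI > 1) and carry the conservative bound 1.01.
PAIR_MIN_CI = {
    pair: (min(ci for _, _, ci in rows) if rows else 1.01)
    for pair, rows in CI_OBSERVATIONS.items()
}

#: Reported single-agent IC50s (umol/L); None encodes "> 100" (above range).
REPORTED_IC50 = {
    "Myricetin": None,
    "Nobiletin": 23.93,
    "Fisetin": 31.19,
    "Celecoxib": None,
    "Hydroxychloroquine": 79.43,
}


def count_synergistic_pairs(cutoff: float = 0.7) -> int:
    """Number of tested pairs whose minimum CI falls below ``cutoff``."""
    return sum(1 for ci in PAIR_MIN_CI.values() if ci < cutoff)
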