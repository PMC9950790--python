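"""End-to-end desk-scale pipeline runs on a synthetic universe.

Glues the stages together: generate universe -> featurize all pairs ->
plant labels -> screen features (tests + resampled RFE frequencies) ->
train the resampled ensemble on the retained features -> evaluate.  Used by
the command-line interface, the recovery tests and the acceptance script.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .ensemble import ResampledEnsemble, train_resampled_ensemble
from .feature_screen import FeatureScreenReport, screen_features
from .io_core import FEATURE_NAMES, RunConfig, derive_seed
from .pair_features import UniverseFeaturizer
from .synthetic_data import PlantedLabelModel, UniverseSpec, generate_universe, plant_labels

logger = logging.getLogger("synergyscreen")

#: Desk-scale run configuration: R = 50 resamples, 5-fold single-repeat CV
#: inside each member, lighter forests and 3-fold CV inside the RFE.
#: RunConfig() defaults keep the full-scale protocol (R = 1000, 3 x 10-fold,
#: 70% cutoff, 5-fold RFE).
def toy_config(master_seed: int = 0) -> RunConfig:
    return RunConfig(n_resamples=50, cv_folds=5, cv_repeats=1,
                     rfe_ntree=10, rfe_cv_folds=3, master_seed=master_seed)


@dataclass
class PipelineResult:
    features: pd.DataFrame
    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]
    screen: FeatureScreenReport
    ensemble: ResampledEnsemble | None


def run_synthetic_pipeline(master_seed: int, config: RunConfig | None = None,
                           spec: UniverseSpec | None = None,
                           label_model: PlantedLabelModel | None = None,
                           classifier_spec: str = "rf",
                           with_cv: bool = True,
                           train_ensemble: bool = True) -> PipelineResult:
    """One full planted-signal pipeline run, reproducible from master_seed."""
    config = config or toy_config(master_seed)
    spec = spec or UniverseSpec(seed=derive_seed(master_seed, "universe"))
    label_model = label_model or PlantedLabelModel(
        seed=derive_seed(master_seed, "labels"))

    drugs, context = generate_universe(spec)
    featurizer = UniverseFeaturizer(drugs, context, config)
    ids = sorted(d.drug_id for d in drugs)
    all_pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    features = featurizer.featurize_pairs(all_pairs)

    positives, negatives = plant_labels(features[FEATURE_NAMES], label_model)
    screen = screen_features(features, positives, negatives, config,
                             n_resamples=config.n_resamples)
    ensemble = None
    if train_ensemble:
        subset = screen.selected_features or FEATURE_NAMES
        ensemble = train_resampled_ensemble(positives, negatives, features, config,
                                            classifier_spec=classifier_spec,
                                            feature_subset=subset, with_cv=with_cv)
    return PipelineResult(features=features, positives=positives,
                          negatives=negatives, screen=screen, ensemble=ensemble)
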