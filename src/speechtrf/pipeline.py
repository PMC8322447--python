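"""End-to-end convenience wrappers tying the stages together.

simulate -> stimulus matrices -> (preprocess) -> TRFs per scheme ->
feature table -> screening -> nested-CV LASSO prediction.
"""

from __future__ import annotations

import numpy as np

from . import prediction as pred
from .components import FeatureTable, assemble_feature_table, default_manifest
from .stimulus import SCHEMES, build_stimulus_matrix
from .synthetic import SyntheticCohort
from .trf import LagAxis, TRFSet, estimate_trfs

__all__ = ["estimate_cohort_trfs", "cohort_feature_table", "predict_scores"]

#: Schemes whose late-component features are computed from open-class words
#: only; their TRFs are estimated from open-restricted stimulus matrices.
OPEN_RESTRICTED_SCHEMES = ("word_position", "speech_rate")


def estimate_cohort_trfs(cohort: SyntheticCohort, lam: float, *,
                         schemes=("word_class",),
                         include_phonemes: bool | None = None,
                         restrict_open: bool = True,
                         ) -> dict[str, list[TRFSet]]:
    """Per-participant TRF sets for each requested scheme.

    Stimulus matrices are rebuilt per scheme from the cohort's annotations;
    ``word_position`` and ``speech_rate`` matrices are restricted to
    open-class words when ``restrict_open`` (the mode used for
    late-component feature extraction).
    """
    lag_axis = cohort.lag_axis
    if include_phonemes is None:
        include_phonemes = "short_vowel" in cohort.stimuli[0].feature_names
    out: dict[str, list[TRFSet]] = {}
    for scheme in schemes:
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}")
        word_filter = ("open" if restrict_open and
                       scheme in OPEN_RESTRICTED_SCHEMES else "all")
        stimuli = [build_stimulus_matrix(a, scheme, lag_axis.fs,
                                         word_filter=word_filter,
                                         include_phonemes=include_phonemes)
                   for a in cohort.annotations]
        out[scheme] = [
            estimate_trfs(list(zip(stimuli, trials)), lam, lag_axis=lag_axis,
                          channel_names=cohort.channels,
                          participant_id=f"p{p:03d}")
            for p, trials in enumerate(cohort.recordings)]
    return out


def cohort_feature_table(cohort: SyntheticCohort, lam: float, *,
                         schemes=("word_class",), manifest=None
                         ) -> FeatureTable:
    """Estimate TRFs and assemble the feature table in one step.

    ``manifest=None`` uses the full 117-entry default (which needs all four
    schemes); pass a reduced manifest for single-scheme studies.
    """
    trfsets = estimate_cohort_trfs(cohort, lam, schemes=schemes)
    if manifest is None:
        manifest = default_manifest()
    manifest = [e for e in manifest if e.scheme in trfsets]
    return assemble_feature_table(trfsets, cohort.scores, manifest)


def predict_scores(table: FeatureTable, *, threshold: float = 0.2,
                   grid: np.ndarray | None = None, inner_folds: int = 10,
                   seed: int = 0):
    """Screen -> z-score -> nested-CV LASSO; returns (result, screened)."""
    screened = pred.screen_features(table, threshold)
    cols = pred.selected_columns(screened)
    if not cols:
        raise pred.PredictionError("no feature passed the screening threshold")
    df = pred.zscore(table.table, cols)
    result = pred.nested_cv_predict(df, cols, grid=grid,
                                    inner_folds=inner_folds, seed=seed)
    return result, screened
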