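"""Trained model libraries and prediction reports.

A model library maps GO terms to trained, calibrated classifiers plus a
log of terms discarded during training.  Prediction turns a protein's
feature vector into one posterior probability per modelled term; the
"displayed" subset is the set of terms whose posterior exceeds 0.5,
while the full posterior list remains available.  Reports sort
high-reliability (H) models first, then by descending posterior.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .features import FeatureVector
from .training import Metrics, TermClassifierResults, TermModel

logger = logging.getLogger(__name__)

DISPLAY_THRESHOLD = 0.5


@dataclass
class ModelLibrary:
    """A collection of per-term models plus discard records."""

    models: dict[str, TermModel] = field(default_factory=dict)
    discarded: dict[str, dict] = field(default_factory=dict)

    def add_result(self, result: TermClassifierResults) -> None:
        if result.model is not None:
            self.models[result.term] = result.model
        else:
            m = result.holdout.metrics
            self.discarded[result.term] = {
                "reason": "holdout_mcc_below_threshold",
                "holdout_metrics": list(m),
                "kernel": result.selected_kernel.kind,
                "k": result.k,
                "seed": result.seed,
            }
            logger.info("term %s discarded (holdout mcc %.3f)",
                        result.term, m.mcc)

    def __len__(self) -> int:
        return len(self.models)

    def __contains__(self, term: str) -> bool:
        return term in self.models

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "format": "seqfunc-model-library/1",
            "models": {t: m.to_dict() for t, m in sorted(self.models.items())},
            "discarded": self.discarded,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle)

    @classmethod
    def load(cls, path) -> "ModelLibrary":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(models={t: TermModel.from_dict(d)
                           for t, d in payload["models"].items()},
                   discarded=payload.get("discarded", {}))


def predict(library: ModelLibrary, vector: FeatureVector,
            display_threshold: float = DISPLAY_THRESHOLD) -> pd.DataFrame:
    """Score one protein against every model in the library.

    Returns a frame with one row per modelled term: term, name,
    namespace, posterior, reliability and the display flag
    (posterior strictly greater than the threshold).  Rows are sorted
    H-first, then by descending posterior.
    """
    rows = []
    for term, model in library.models.items():
        posterior = model.posterior(vector)
        rows.append({
            "term": term,
            "name": model.name,
            "namespace": model.namespace,
            "posterior": posterior,
            "reliability": model.reliability,
            "displayed": posterior > display_threshold,
        })
    frame = pd.DataFrame(
        rows, columns=["term", "name", "namespace", "posterior",
                       "reliability", "displayed"])
    if len(frame):
        frame = frame.sort_values(
            by=["reliability", "posterior", "term"],
            ascending=[True, False, True],  # 'H' < 'L'
            kind="mergesort").reset_index(drop=True)
    return frame
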