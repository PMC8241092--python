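"""Decision curve analysis: net benefit over a grid of threshold probabilities.

At a threshold probability t a patient is treated iff their predicted risk
is at least t (ties at t treated, i.e. the rule is inclusive). The net
benefit of the model is

    NB(t) = TP/n - FP/n * t / (1 - t)

— true positives credited in full, false positives debited at the odds a
clinician who would act at threshold t implicitly accepts. Reference
policies: treat-none (NB = 0) and treat-all
(NB = prevalence - (1 - prevalence) * t/(1-t)). Net benefit can never
exceed the event prevalence; a model worth using dominates both references
over the clinically relevant threshold range. The default grid,
0.01-0.50 in steps of 0.01, spans plausible treatment thresholds for
in-hospital mortality after STEMI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discrimination import _as_arrays
from .errors import ValidationError

__all__ = ["NetBenefitCurve", "net_benefit", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = np.round(np.arange(0.01, 0.505, 0.01), 10)


@dataclass(frozen=True)
class NetBenefitCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray

    def to_frame(self, model_name: str = "model") -> pd.DataFrame:
        """Tidy table (threshold, nb_model, nb_all, nb_none, model_name)
        ready for plotting."""
        return pd.DataFrame({
            "threshold": self.thresholds, "nb_model": self.nb_model,
            "nb_all": self.nb_all, "nb_none": self.nb_none,
            "model_name": model_name})


def net_benefit(predicted, label, thresholds=DEFAULT_THRESHOLDS) -> NetBenefitCurve:
    """Net-benefit curve of predicted probabilities for a binary outcome."""
    p, y = _as_arrays(predicted, label)
    if not ((p > 0) & (p < 1)).all():
        raise ValidationError("predicted probabilities must lie strictly in (0,1)")
    t = np.asarray(thresholds, dtype=float)
    if not ((t > 0) & (t < 1)).all():
        raise ValidationError("thresholds must lie strictly in (0,1)")
    n = len(p)
    prev = y.mean()
    odds = t / (1.0 - t)
    treated = p[None, :] >= t[:, None]
    tp = (treated & y[None, :]).sum(axis=1) / n
    fp = (treated & ~y[None, :]).sum(axis=1) / n
    return NetBenefitCurve(
        thresholds=t,
        nb_model=tp - fp * odds,
        nb_all=prev - (1.0 - prev) * odds,
        nb_none=np.zeros_like(t))
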