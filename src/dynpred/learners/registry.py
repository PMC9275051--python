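"""Named learner catalogue: the eleven survival sub-methods.

Each method name maps to a constructor; :func:`make_learner` builds a fresh
unfitted learner from a :class:`LearnerSpec` (method name + overrides +
seed), so cross-validation layers can re-instantiate learners per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cox import CoxLearner
from .penalized import PenalizedCoxLearner
from .rsf import RSFLearner
from .spls import SPLSDRLearner

__all__ = ["LearnerSpec", "make_learner", "METHODS", "default_specs"]

_FACTORIES = {
    "cox_all": lambda seed, kw: CoxLearner(select=False, **kw),
    "cox_select": lambda seed, kw: CoxLearner(select=True, **kw),
    "pcox_lasso": lambda seed, kw: PenalizedCoxLearner("lasso", seed=seed, **kw),
    "pcox_ridge": lambda seed, kw: PenalizedCoxLearner("ridge", seed=seed, **kw),
    "pcox_elastic": lambda seed, kw: PenalizedCoxLearner("elastic", seed=seed, **kw),
    "spls_nosparse": lambda seed, kw: SPLSDRLearner("none", seed=seed, **kw),
    "spls_maxsparse": lambda seed, kw: SPLSDRLearner("max", seed=seed, **kw),
    "spls_optimize": lambda seed, kw: SPLSDRLearner("optimize", seed=seed, **kw),
    "rsf_default": lambda seed, kw: RSFLearner("default", seed=seed, **kw),
    "rsf_optimize": lambda seed, kw: RSFLearner("optimize", seed=seed, **kw),
    "rsf_select": lambda seed, kw: RSFLearner("select", seed=seed, **kw),
}

METHODS = tuple(_FACTORIES)


@dataclass(frozen=True)
class LearnerSpec:
    """A recipe for one survival learner."""

    method: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.method not in _FACTORIES:
            raise ValueError(
                f"unknown method {self.method!r}; known: {sorted(_FACTORIES)}")


def make_learner(spec: LearnerSpec):
    return _FACTORIES[spec.method](spec.seed, dict(spec.params))


def default_specs(methods=METHODS, seed: int = 0, **common):
    return [LearnerSpec(m, dict(common), seed) for m in methods]
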