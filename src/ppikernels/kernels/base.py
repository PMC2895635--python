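"""Base class for pairwise instance kernels.

Kernels are scikit-learn-style estimators (parameters in ``__init__``,
``get_params``/``set_params`` from ``BaseEstimator``) that map two candidate
instances to a similarity score.  Each kernel splits its work into
``prepare`` (instance -> cached representation, computed once per instance by
the Gram builder) and ``similarity`` (representation pair -> score), so Gram
matrices over n instances cost n preparations and n(n+1)/2 comparisons.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator

from ..model import CandidateInstance


class PairwiseKernel(BaseEstimator):
    #: short registry name (the field's usual abbreviation)
    name: str = "kernel"

    def prepare(self, instance: CandidateInstance):
        raise NotImplementedError

    def similarity(self, rep_x, rep_y) -> float:
        raise NotImplementedError

    def __call__(self, x: CandidateInstance, y: CandidateInstance) -> float:
        return self.similarity(self.prepare(x), self.prepare(y))
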