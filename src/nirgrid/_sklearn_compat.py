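"""Optional scikit-learn integration.

The estimators in this package follow the scikit-learn protocol
(get_params/set_params, fit/transform/predict, trailing-underscore fitted
attributes) without inheriting from scikit-learn, so the library has no hard
dependency on it. Modern scikit-learn model-selection utilities additionally
query ``__sklearn_tags__``; these helpers synthesize the appropriate tags
on demand, importing scikit-learn only when it is the caller.
"""

from __future__ import annotations


def classifier_tags():
    from sklearn.base import BaseEstimator, ClassifierMixin

    class _Proto(ClassifierMixin, BaseEstimator):
        pass

    return _Proto().__sklearn_tags__()


def transformer_tags():
    from sklearn.base import BaseEstimator, TransformerMixin

    class _Proto(TransformerMixin, BaseEstimator):
        pass

    return _Proto().__sklearn_tags__()
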