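"""The radiomics signature: a sigmoid of a LASSO-weighted feature combination.

``Rad_score = sigmoid(intercept + sum_k coef_k * feature_k)`` with the
standard logistic ``sigmoid(x) = 1 / (1 + exp(-x))``, so scores lie in
(0, 1) and higher scores indicate better 5-year survival odds.

:func:`published_signature` returns the frozen 8-term reference model of
the rectal-cancer study this package re-implements (intercept -0.664).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import FeatureKey, FeatureVector

__all__ = ["SignatureModel", "sigmoid", "rad_score", "published_signature"]


def sigmoid(x: float | np.ndarray) -> float | np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class SignatureModel:
    """Intercept + ordered weighted feature terms behind a sigmoid link."""

    intercept: float
    terms: list[tuple[FeatureKey, float]]
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.terms) >= 11:
            raise ValueError("signature exceeds the 10:1 feature cap (>= 11 terms)")
        if not np.isfinite(self.intercept):
            raise ValueError("non-finite intercept")
        for key, coef in self.terms:
            if not np.isfinite(coef):
                raise ValueError(f"non-finite coefficient for {key}")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "intercept": self.intercept,
            "terms": [[str(k), c] for k, c in self.terms],
            "note": self.note,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SignatureModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        payload = json.loads(text)
        return cls(
            intercept=float(payload["intercept"]),
            terms=[(FeatureKey.parse(k), float(c)) for k, c in payload["terms"]],
            note=payload.get("note", ""),
        )


def rad_score(features: FeatureVector | dict[FeatureKey, float],
              model: SignatureModel) -> float:
    """Evaluate the signature on one patient's feature vector."""
    values = features.values if isinstance(features, FeatureVector) else features
    eta = model.intercept
    for key, coef in model.terms:
        if key not in values:
            raise KeyError(f"feature vector is missing signature key {key}")
        eta += coef * values[key]
    return float(sigmoid(eta))


def published_signature() -> SignatureModel:
    """The frozen 8-term reference signature (printed formula, verbatim).

    Term keys follow the documented channel mapping: the dynamic
    contrast-enhanced phases LAVA2/LAVA3 are the raw L2/L3 channels; GLCM
    terms carry distance 1.  Where the source's prose feature list and its
    printed formula disagree (T1w HLH-vs-HLL histogram max; the two T2w
    terms), the printed formula is authoritative — see ``note``.
    """
    terms = [
        (FeatureKey("L2", "native", "histogram", "skewness"), 0.106),
        (FeatureKey("L3", "HLL", "histogram", "max"), -0.029),
        (FeatureKey("L3", "native", "glcm", "difference_entropy", 1), 0.022),
        (FeatureKey("T1w", "native", "glrlm", "lre"), 0.067),
        (FeatureKey("T1w", "HLH", "histogram", "max"), 0.05),
        (FeatureKey("T2w", "native", "glrlm", "lre"), -0.082),
        (FeatureKey("T2w", "HLH", "histogram", "p40"), 0.05),
        (FeatureKey("ADC", "native", "glcm", "imc1", 1), -0.092),
    ]
    return SignatureModel(
        intercept=-0.664,
        terms=terms,
        note=(
            "Frozen reference coefficients. The source's prose lists "
            "T1w(HLL_HistMax) and T2w(LLL_Hist10%), but its printed formula "
            "uses T1w(HLH HistMax), T2w(LongRunEmphasis) and T2w(HLH Hist40%); "
            "the formula is adopted. LAVA2/LAVA3 resolved to raw DCE phases "
            "L2/L3; GLCM terms at distance 1."
        ),
    )
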