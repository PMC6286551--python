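"""Fitted prognostic model: per-covariate codings plus Cox weights.

The prognostic index (PI) is the Cox linear predictor — the weighted
sum of transformed covariates — centered so that a reference patient
(35 years, 20 mm tumor, 0 positive nodes) has PI = 0 and hence relative
hazard exp(PI) = 1.00 by definition.  Serializing the model captures
the transforms, weights and reference exactly, so the PI of any new
patient is reproducible bit-for-bit — the contract external validation
relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coxladder.synthetic_data import REFERENCE_PATIENT
from coxladder.transforms import transform_from_dict


@dataclass
class PrognosticModel:
    """Per-covariate transforms with fitted log relative-hazard weights."""

    transforms: dict  # covariate name -> CategoryScheme | FPSpec | RCSSpec
    weights: np.ndarray
    reference: dict = field(default_factory=lambda: dict(REFERENCE_PATIENT))
    covariance: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != self.n_cols:
            raise ValueError(
                f"weight vector length {self.weights.size} does not match "
                f"total basis dimension {self.n_cols}")

    @property
    def covariates(self) -> list:
        return list(self.transforms)

    @property
    def n_cols(self) -> int:
        return sum(t.n_cols for t in self.transforms.values())

    def design(self, cohort: pd.DataFrame) -> np.ndarray:
        """Stacked basis columns for every covariate, in transform order."""
        blocks = [t.basis(cohort[name].to_numpy())
                  for name, t in self.transforms.items()]
        return np.column_stack(blocks) if blocks else np.empty((len(cohort), 0))

    def column_slices(self) -> dict:
        """Covariate name -> slice of its columns in the stacked design."""
        out, start = {}, 0
        for name, t in self.transforms.items():
            out[name] = slice(start, start + t.n_cols)
            start += t.n_cols
        return out

    def _reference_row(self) -> pd.DataFrame:
        return pd.DataFrame({k: [v] for k, v in self.reference.items()})

    def prognostic_index(self, cohort: pd.DataFrame) -> np.ndarray:
        """PI = weighted sum of transformed covariates, zero at reference."""
        ref = float((self.design(self._reference_row()) @ self.weights).item())
        return self.design(cohort) @ self.weights - ref

    def relative_hazard(self, cohort: pd.DataFrame) -> np.ndarray:
        """exp(PI): hazard relative to the reference patient."""
        return np.exp(self.prognostic_index(cohort))

    def to_dict(self) -> dict:
        return {
            "transforms": {k: t.to_dict() for k, t in self.transforms.items()},
            "weights": self.weights.tolist(),
            "reference": dict(self.reference),
            "covariance": (None if self.covariance is None
                           else np.asarray(self.covariance).tolist()),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrognosticModel":
        return cls(
            transforms={k: transform_from_dict(t)
                        for k, t in d["transforms"].items()},
            weights=np.asarray(d["weights"], dtype=float),
            reference=dict(d["reference"]),
            covariance=(None if d.get("covariance") is None
                        else np.asarray(d["covariance"], dtype=float)),
            meta=d.get("meta", {}),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PrognosticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
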