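"""Variance-component containers shared by the fitting and reporting code."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VarianceComponents"]


def _as_K(value) -> np.ndarray:
    K = np.atleast_2d(np.asarray(value, dtype=float))
    if K.shape[0] != K.shape[1]:
        raise ValueError("coefficient covariance must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("coefficient covariance must be symmetric")
    return 0.5 * (K + K.T)


@dataclass
class VarianceComponents:
    """Per-term (co)variances plus the residual structure.

    ``terms`` maps a random-term name (``aF``, ``peF``, ``peM``) to its
    coefficient covariance matrix K; scalar variances are stored as
    1x1 matrices.  ``residual`` is a vector with one variance per
    residual class (length 1 when homogeneous), or ``None`` when the
    residual is structurally fixed (threshold working model).
    """

    terms: dict = field(default_factory=dict)
    residual: np.ndarray | None = None
    residual_labels: tuple = ()

    def __post_init__(self):
        self.terms = {k: _as_K(v) for k, v in self.terms.items()}
        if self.residual is not None:
            self.residual = np.atleast_1d(np.asarray(self.residual, dtype=float))
            if np.any(self.residual < 0):
                raise ValueError("residual variances must be >= 0")

    @classmethod
    def from_scalars(cls, sigma2_a=None, sigma2_pef=None, sigma2_pem=None,
                     sigma2_e=None) -> "VarianceComponents":
        terms = {}
        if sigma2_a is not None:
            terms["aF"] = [[float(sigma2_a)]]
        if sigma2_pef is not None:
            terms["peF"] = [[float(sigma2_pef)]]
        if sigma2_pem is not None:
            terms["peM"] = [[float(sigma2_pem)]]
        return cls(terms=terms, residual=None if sigma2_e is None else [float(sigma2_e)])

    def K(self, name: str) -> np.ndarray:
        return self.terms[name]

    def scalar(self, name: str) -> float:
        K = self.terms[name]
        if K.shape != (1, 1):
            raise ValueError(f"term {name!r} is a matrix, not a scalar variance")
        return float(K[0, 0])

    @property
    def sigma2_e(self) -> float:
        if self.residual is None:
            raise ValueError("residual is structurally fixed for this fit")
        if len(self.residual) != 1:
            raise ValueError("residual is heterogeneous; use .residual")
        return float(self.residual[0])

    def to_dict(self) -> dict:
        out = {
            "terms": {
                k: {"order": v.shape[0] - 1, "K_row_major": v.ravel().tolist()}
                for k, v in self.terms.items()
            }
        }
        if self.residual is not None:
            out["residual"] = self.residual.tolist()
            if self.residual_labels:
                out["residual_labels"] = list(self.residual_labels)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "VarianceComponents":
        terms = {}
        for k, v in d.get("terms", {}).items():
            m = v["order"] + 1
            terms[k] = np.asarray(v["K_row_major"], dtype=float).reshape(m, m)
        residual = d.get("residual")
        return cls(terms=terms, residual=residual,
                   residual_labels=tuple(d.get("residual_labels", ())))
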