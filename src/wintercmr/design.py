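"""Model specification and design matrices for CJS survival/detection models.

A model is written in the field's compact notation, e.g.

    {phi(t x cond) p(g x ice + complex x t)}

(the Greek phi and the multiplication sign are accepted too).  ``phi`` terms
describe apparent survival over the T-1 intervals, ``p`` terms the detection
probability at occasions 2..T, both on the logit scale.  Factors are either
categorical (``g`` fish group, ``t`` time) or continuous — individual
covariates such as ``cond`` (Fulton condition) or ``complex`` (structural
complexity), and time covariates such as ``ice`` (mean ice thickness), which
enter as linear temporal constraints.

A crossed term ``f1 x f2 x ...`` expands to the cell indicators of its
categorical factors combined with every product over subsets of its
continuous factors, so ``t x cond`` with 13 intervals yields 13 per-interval
intercepts plus 13 per-interval condition slopes, and ``g x ice`` yields 3
group intercepts plus 3 group-specific ice slopes.  Redundant columns across
terms are permitted; estimability is resolved numerically at fit time.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histories import GROUPS

__all__ = ["DesignSpec", "CJSData", "DesignMatrices", "build_design", "ModelParseError"]

CATEGORICAL = ("g", "t")


class ModelParseError(ValueError):
    pass


@dataclass(frozen=True)
class DesignSpec:
    """Parsed model structure: additive terms of crossed factors."""

    phi_terms: tuple[tuple[str, ...], ...]
    p_terms: tuple[tuple[str, ...], ...]

    @classmethod
    def parse(cls, text: str) -> "DesignSpec":
        s = text.strip()
        s = s.replace("φ", "phi").replace("ϕ", "phi")
        s = s.strip("{}").strip()
        m = re.fullmatch(r"phi\s*\((?P<phi>[^()]*)\)\s*p\s*\((?P<p>[^()]*)\)", s)
        if m is None:
            pos = len(text) - len(text.lstrip())
            raise ModelParseError(
                f"cannot parse model string {text!r} (expected 'phi(...)p(...)', position {pos})"
            )
        return cls(phi_terms=cls._terms(m["phi"]), p_terms=cls._terms(m["p"]))

    @staticmethod
    def _terms(expr: str) -> tuple[tuple[str, ...], ...]:
        terms = []
        for raw in expr.split("+"):
            # cross operator: '×', '*', or a whitespace-delimited 'x'
            factors = [f for f in re.split(r"\s*[×*]\s*|\s+x\s+", raw.strip()) if f]
            if not factors:
                raise ModelParseError(f"empty term in {expr!r}")
            for f in factors:
                if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*|1", f):
                    raise ModelParseError(f"bad factor {f!r} at position {expr.find(f)} in {expr!r}")
            terms.append(tuple(factors))
        return tuple(terms)

    def to_string(self, ascii_only: bool = False) -> str:
        cross = " x " if ascii_only else " × "
        phi_sym = "phi" if ascii_only else "φ"

        def side(terms):
            return " + ".join(cross.join(t) for t in terms)

        return f"{{{phi_sym}({side(self.phi_terms)})p({side(self.p_terms)})}}"

    def __str__(self) -> str:  # round-trips through parse
        return self.to_string()

    def covariate_names(self) -> set[str]:
        out = set()
        for term in self.phi_terms + self.p_terms:
            out.update(f for f in term if f not in CATEGORICAL and f != "1")
        return out


@dataclass
class CJSData:
    """Encounter matrix plus covariates, the input to model fitting.

    ``histories`` is an (n, T) 0/1 matrix whose first column is the marking
    occasion (all ones for fish released at occasion 1).  ``covariates`` holds
    one row per fish; ``time_covariates`` maps a name to a length T-1 vector
    aligned with intervals (for phi) and with occasions 2..T (for p).
    """

    histories: np.ndarray
    groups: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    time_covariates: dict = field(default_factory=dict)
    fish_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.histories = np.asarray(self.histories, dtype=int)
        self.groups = np.asarray(self.groups)
        if self.histories.ndim != 2:
            raise ValueError("histories must be a 2-D matrix")
        if len(self.groups) != self.n:
            raise ValueError("groups length must match histories")
        if not (self.histories[:, 0] == 1).all():
            raise ValueError("all histories must start with the marking detection")
        for name, vec in self.time_covariates.items():
            if len(np.asarray(vec)) != self.T - 1:
                raise ValueError(f"time covariate {name!r} must have length T-1 = {self.T - 1}")
        if self.fish_ids is None:
            self.fish_ids = np.array([f"f{i}" for i in range(self.n)])

    @property
    def n(self) -> int:
        return self.histories.shape[0]

    @property
    def T(self) -> int:
        return self.histories.shape[1]

    @property
    def group_levels(self) -> list[str]:
        present = set(self.groups.tolist())
        ordered = [g for g in GROUPS if g in present]
        return ordered + sorted(present - set(ordered))

    @property
    def last_detection(self) -> np.ndarray:
        """0-based occasion index of each fish's final detection."""
        T = self.T
        rev = self.histories[:, ::-1]
        return T - 1 - rev.argmax(axis=1)

    @property
    def n_released(self) -> int:
        return self.n


@dataclass
class DesignMatrices:
    """Per-individual design arrays: X_phi (n, T-1, q_phi), X_p (n, T-1, q_p)."""

    spec: DesignSpec
    X_phi: np.ndarray
    X_p: np.ndarray
    phi_labels: list[str]
    p_labels: list[str]

    @property
    def n_params(self) -> int:
        return self.X_phi.shape[2] + self.X_p.shape[2]

    def split(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q = self.X_phi.shape[2]
        return beta[:q], beta[q:]

    @property
    def labels(self) -> list[str]:
        return [f"phi:{l}" for l in self.phi_labels] + [f"p:{l}" for l in self.p_labels]


def _factor_columns(
    term: tuple[str, ...], data: CJSData, n_int: int, side: str
) -> tuple[list[np.ndarray], list[str]]:
    """Expand one crossed term into (n, n_int) column arrays with labels."""
    n = data.n
    cats = [f for f in term if f in CATEGORICAL]
    conts = [f for f in term if f not in CATEGORICAL and f != "1"]

    # cell indicator matrices of the categorical crossing
    cells: list[tuple[np.ndarray, str]] = [(np.ones((n, n_int)), "")]
    for c in cats:
        new = []
        if c == "g":
            for lev in data.group_levels:
                ind = (data.groups == lev).astype(float)[:, None] * np.ones((1, n_int))
                new.append((ind, f"g={lev}"))
        else:  # t
            for k in range(n_int):
                ind = np.zeros((n, n_int))
                ind[:, k] = 1.0
                new.append((ind, f"t{k + 1}"))
        cells = [
            (base * ind, ":".join(filter(None, [blab, lab])))
            for base, blab in cells
            for ind, lab in new
        ]

    # continuous factor values broadcast to (n, n_int)
    def values(name: str) -> np.ndarray:
        if name in data.time_covariates:
            v = np.asarray(data.time_covariates[name], dtype=float)
            return np.broadcast_to(v, (n, n_int)).copy()
        if name in data.covariates.columns:
            v = data.covariates[name].to_numpy(dtype=float)
            return np.broadcast_to(v[:, None], (n, n_int)).copy()
        raise ModelParseError(f"unknown covariate {name!r} in {side} term {'x'.join(term)}")

    cols, labels = [], []
    for r in range(len(conts) + 1):
        for subset in itertools.combinations(conts, r):
            prod = np.ones((n, n_int))
            for name in subset:
                prod = prod * values(name)
            for cell, clab in cells:
                cols.append(cell * prod)
                labels.append(":".join(filter(None, [clab, *subset])) or "1")
    return cols, labels


def build_design(spec: DesignSpec, data: CJSData) -> DesignMatrices:
    """Expand a model specification into per-individual design arrays."""
    n_int = data.T - 1

    def side(terms, name):
        cols, labels = [], []
        for term in terms:
            c, l = _factor_columns(term, data, n_int, name)
            cols.extend(c)
            labels.extend(l)
        X = np.stack(cols, axis=2) if cols else np.zeros((data.n, n_int, 0))
        return X, labels

    X_phi, phi_labels = side(spec.phi_terms, "phi")
    X_p, p_labels = side(spec.p_terms, "p")
    return DesignMatrices(spec=spec, X_phi=X_phi, X_p=X_p, phi_labels=phi_labels, p_labels=p_labels)
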