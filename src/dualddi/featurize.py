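"""Atom featurization schemes.

A scheme turns an RDKit atom into a fixed-width numeric vector; the width d0
is constant for every molecule featurized under the same scheme, so graphs
from one scheme can share an encoder.  Schemes are registered by name and the
name is stored in model checkpoints, keeping d0 stable across sessions.

``atoms-v1`` (default, d0 = 27) encodes, per heavy atom:

* element one-hot over {C, N, O, S, F, Cl, Br, I, P} plus an "other" slot,
* heavy-atom degree one-hot 0-5 (degree > 5 clips to the last slot),
* formal charge as an integer clipped to [-2, 2],
* hybridization one-hot over {sp, sp2, sp3, other},
* aromaticity flag,
* total attached hydrogens one-hot 0-4 (clipped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from rdkit import Chem

__all__ = ["FeaturizationScheme", "register_scheme", "get_scheme", "DEFAULT_SCHEME"]


@dataclass(frozen=True)
class FeaturizationScheme:
    name: str
    n_features: int
    atom_features: Callable[[Chem.Atom], np.ndarray]


_REGISTRY: dict[str, FeaturizationScheme] = {}


def register_scheme(scheme: FeaturizationScheme) -> None:
    if scheme.name in _REGISTRY:
        raise ValueError(f"featurization scheme {scheme.name!r} already registered")
    _REGISTRY[scheme.name] = scheme


def get_scheme(name: str) -> FeaturizationScheme:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown featurization scheme {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P"]
_HYBRID = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
]


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[index] = 1.0
    return v


def _atoms_v1(atom: Chem.Atom) -> np.ndarray:
    sym = atom.GetSymbol()
    elem = _one_hot(_ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS),
                    len(_ELEMENTS) + 1)
    degree = _one_hot(min(atom.GetDegree(), 5), 6)
    charge = np.array([float(np.clip(atom.GetFormalCharge(), -2, 2))])
    hyb = atom.GetHybridization()
    hybrid = _one_hot(_HYBRID.index(hyb) if hyb in _HYBRID else len(_HYBRID),
                      len(_HYBRID) + 1)
    aromatic = np.array([1.0 if atom.GetIsAromatic() else 0.0])
    n_h = _one_hot(min(atom.GetTotalNumHs(), 4), 5)
    return np.concatenate([elem, degree, charge, hybrid, aromatic, n_h])


register_scheme(FeaturizationScheme("atoms-v1", 27, _atoms_v1))

DEFAULT_SCHEME = "atoms-v1"
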