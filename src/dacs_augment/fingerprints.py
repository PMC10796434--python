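"""Molecular fingerprint backends.

The default backend computes a 1024-bit linear-path fingerprint (paths of
length 1-7 bonds, no branching) with RDKit. Path fingerprints from different
toolkits are not bit-identical, so every :class:`Fingerprint` records the
backend that produced it and similarity is only defined between fingerprints
of equal length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, FrozenSet

DEFAULT_N_BITS = 1024
DEFAULT_BACKEND = "rdkit-path-linear"


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length molecular bit set."""

    bits: FrozenSet[int]
    n_bits: int = DEFAULT_N_BITS
    backend: str = DEFAULT_BACKEND

    def __post_init__(self) -> None:
        if self.n_bits < 1:
            raise ValueError(f"n_bits must be >= 1, got {self.n_bits}")
        bits = frozenset(int(b) for b in self.bits)
        object.__setattr__(self, "bits", bits)
        bad = [b for b in bits if b < 0 or b >= self.n_bits]
        if bad:
            raise ValueError(f"bit indices out of range [0, {self.n_bits}): {sorted(bad)[:5]}")

    def __len__(self) -> int:
        return self.n_bits

    def to_string(self) -> str:
        """Serialize on-bits as a ';'-joined index list (empty string if none set)."""
        return ";".join(str(b) for b in sorted(self.bits))

    @classmethod
    def from_string(cls, text: str, n_bits: int = DEFAULT_N_BITS,
                    backend: str = DEFAULT_BACKEND) -> "Fingerprint":
        text = text.strip()
        bits = frozenset(int(tok) for tok in text.split(";")) if text else frozenset()
        return cls(bits=bits, n_bits=n_bits, backend=backend)


def _rdkit_linear_path(smiles: str, n_bits: int = DEFAULT_N_BITS) -> Fingerprint:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    bv = Chem.RDKFingerprint(mol, minPath=1, maxPath=7, fpSize=n_bits, branchedPaths=False)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), n_bits=n_bits, backend=DEFAULT_BACKEND)


#: Registry of named fingerprint backends: name -> callable(smiles, n_bits) -> Fingerprint.
BACKENDS: dict[str, Callable[[str, int], Fingerprint]] = {
    DEFAULT_BACKEND: _rdkit_linear_path,
}


def fingerprint_from_smiles(smiles: str, n_bits: int = DEFAULT_N_BITS,
                            backend: str = DEFAULT_BACKEND) -> Fingerprint:
    """Compute a fingerprint for ``smiles`` with the named backend.

    Raises
    ------
    ValueError
        If the SMILES cannot be parsed or the backend is unknown.
    """
    try:
        fn = BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown fingerprint backend {backend!r}; "
                         f"known: {sorted(BACKENDS)}") from None
    return fn(smiles, n_bits)
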