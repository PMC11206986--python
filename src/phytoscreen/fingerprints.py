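"""Circular substructure fingerprints and Tanimoto similarity.

Fingerprints are binary Morgan fingerprints of radius 2 (diameter 4 —
ECFP4) folded to 2048 bits by default. Similarity between two
fingerprints A and B is the Tanimoto coefficient

    Tc(A, B) = |A ∩ B| / (|A| + |B| − |A ∩ B|),

computed here in exact integer/rational arithmetic over the on-bit sets,
so comparisons against thresholds such as 0.4 are never subject to
floating-point ordering artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from phytoscreen.errors import ComparabilityError, StructureError

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048


@dataclass(frozen=True)
class Fingerprint:
    """Binary circular fingerprint: the set of on-bit positions plus the
    generation parameters that make two fingerprints comparable."""

    bits: frozenset[int]
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValueError("bit index outside [0, n_bits)")

    @property
    def popcount(self) -> int:
        return len(self.bits)

    def comparable_with(self, other: "Fingerprint") -> bool:
        return self.n_bits == other.n_bits and self.radius == other.radius


# one generator per parameter combination; construction is not free
_GENERATORS: dict[tuple[int, int, bool], object] = {}


def _generator(radius: int, n_bits: int, use_chirality: bool):
    key = (radius, n_bits, use_chirality)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits, includeChirality=use_chirality
        )
    return _GENERATORS[key]


def compute_fingerprint(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    use_chirality: bool = False,
) -> Fingerprint:
    """ECFP-style Morgan fingerprint of a SMILES string.

    Deterministic: any SMILES spelling of the same molecule yields an
    identical bit vector, because hashing operates on the molecular graph,
    not the input string. Chirality flags in the atom invariants are off
    by default and exposed because conventions differ between toolchains.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable structure: {smiles!r}")
    fp = _generator(radius, n_bits, use_chirality).GetFingerprint(mol)
    return Fingerprint(frozenset(fp.GetOnBits()), n_bits=n_bits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> Fraction:
    """Exact Tanimoto coefficient |A∩B| / (|A|+|B|−|A∩B|) as a Fraction.

    Symmetric; 1 iff the (nonempty) bit sets are identical; 0 for disjoint
    sets. Two all-zero fingerprints give 0 by convention — the formula is
    0/0 there, and featureless structures should never be called similar.
    """
    if not a.comparable_with(b):
        raise ComparabilityError(
            f"fingerprint parameters differ: ({a.n_bits}, r{a.radius}) "
            f"vs ({b.n_bits}, r{b.radius})"
        )
    intersection = len(a.bits & b.bits)
    union = a.popcount + b.popcount - intersection
    if union == 0:
        return Fraction(0)
    return Fraction(intersection, union)


def fingerprint_to_hex(fp: Fingerprint) -> str:
    """Hex encoding of the bit vector (little-endian bit order) for caching."""
    value = 0
    for bit in fp.bits:
        value |= 1 << bit
    width = (fp.n_bits + 3) // 4
    return format(value, f"0{width}x")


def fingerprint_from_hex(text: str, n_bits: int, radius: int) -> Fingerprint:
    value = int(text, 16)
    bits = frozenset(i for i in range(n_bits) if value >> i & 1)
    return Fingerprint(bits, n_bits=n_bits, radius=radius)
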