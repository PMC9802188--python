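"""Amino-acid and nucleotide sequence primitives.

Synthetic reference sequences are generated deterministically from stable
string keys so that the shipped catalogs, marker sets, and test fixtures are
reproducible across platforms without bundling FASTA data.
"""

from __future__ import annotations

import functools
import zlib

import numpy as np

# Canonical 20-letter amino-acid alphabet (index order used by all profiles).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

# Index reserved for 'X' / unknown residues: scores as background (0 bits).
X_INDEX = len(AA_ALPHABET)

# Robinson & Robinson style background amino-acid frequencies, normalised.
_BG = np.array(
    [
        0.0788, 0.0151, 0.0535, 0.0668, 0.0397, 0.0696, 0.0220, 0.0580,
        0.0596, 0.0963, 0.0241, 0.0429, 0.0484, 0.0395, 0.0540, 0.0687,
        0.0541, 0.0673, 0.0103, 0.0314,
    ]
)
BACKGROUND = _BG / _BG.sum()


def stable_seed(*parts: object) -> int:
    """Deterministic 31-bit seed from string parts (platform independent)."""
    text = "\x1f".join(str(p) for p in parts)
    return zlib.crc32(text.encode("utf-8")) & 0x7FFFFFFF


def encode_protein(sequence: str) -> np.ndarray:
    """Map a protein string to integer indices; unknown residues -> X slot."""
    return np.fromiter(
        (AA_INDEX.get(aa, X_INDEX) for aa in sequence.upper()),
        dtype=np.int64,
        count=len(sequence),
    )


def random_protein(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(AA_ALPHABET), size=length, p=BACKGROUND)
    return "".join(AA_ALPHABET[i] for i in idx)


@functools.lru_cache(maxsize=None)
def synthetic_protein(key: str, length: int | None = None) -> str:
    """Deterministic synthetic protein for a reference key.

    Length is drawn reproducibly from 180-320 aa when not given, matching
    typical single-domain enzyme sizes.
    """
    rng = np.random.default_rng(stable_seed("cfpscan-ref", key))
    if length is None:
        length = int(rng.integers(180, 321))
    return random_protein(length, rng)


def mutate_protein(sequence: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute residues i.i.d. so expected identity equals ``identity``.

    Substitution-only (no indels): the downstream scorer is ungapped, and the
    generator stays consistent with it.
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity must be in [0, 1], got {identity}")
    out = list(sequence)
    p_sub = 1.0 - identity
    for i, aa in enumerate(out):
        if rng.random() < p_sub:
            # Draw a different residue from the background.
            new = aa
            while new == aa:
                new = AA_ALPHABET[rng.choice(len(AA_ALPHABET), p=BACKGROUND)]
            out[i] = new
    return "".join(out)


def shuffle_protein(sequence: str, rng: np.random.Generator) -> str:
    chars = list(sequence)
    rng.shuffle(chars)
    return "".join(chars)


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random nucleotide sequence with i.i.d. bases at the given GC fraction."""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=probs)
    return "".join("ACGT"[i] for i in idx)


def gc_fraction(sequence: str) -> float:
    if not sequence:
        raise ValueError("empty sequence has no GC fraction")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    return gc / len(seq)
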