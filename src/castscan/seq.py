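"""Small DNA-string utilities shared across modules.

Sequences are plain upper-case Python strings over {A,C,G,T}; the simulator
never emits N, and all coordinate arithmetic is 0-based, half-open.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """Random DNA of the given length with expected GC fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p / p.sum()))


def substitute_base(base: str, rng: np.random.Generator) -> str:
    """A base drawn uniformly from the three alternatives to ``base``."""
    choices = [b for b in DNA_ALPHABET if b != base]
    return choices[rng.integers(3)]


def add_substitution_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Inject i.i.d. substitution errors at per-base probability ``rate``.

    Length is preserved: the simulator's sequencing-error model is
    substitution-only, so indel truth stays unambiguous.
    """
    if rate <= 0 or not seq:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        out[i] = substitute_base(out[i], rng)
    return "".join(out)


def find_all_exact(query: str, target: str) -> list[int]:
    """All start positions of exact occurrences of ``query`` in ``target``."""
    hits = []
    i = target.find(query)
    while i != -1:
        hits.append(i)
        i = target.find(query, i + 1)
    return hits


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))
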