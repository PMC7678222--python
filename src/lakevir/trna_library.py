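"""Bundled canonical tRNA sequence set (synthetic).

A fixed, deterministically generated library of tRNA-length nucleotide
sequences standing in for a canonical prokaryote tRNA gene set.  The
sequences are synthetic: tRNA detection in this pipeline is homology to
this bundled set, and the synthetic-community generator plants tRNA genes
from the same set, so only the identity and fixedness of the library
matter, not covariance-model realism.  One entry per amino-acid
isoacceptor class (two for Leu/Ser/Arg), lengths 72-90 nt.
"""

from __future__ import annotations

import numpy as np

_AA3 = [
    "Ala", "Arg", "Arg2", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His",
    "Ile", "Leu", "Leu2", "Lys", "Met", "fMet", "Phe", "Pro", "Ser", "Ser2",
    "Thr", "Trp", "Tyr", "Val", "SeC", "Ala2", "Gly2", "Thr2", "Val2", "Ile2",
    "Asn2", "Asp2", "Cys2", "Gln2", "Glu2", "His2", "Lys2", "Phe2", "Pro2", "Trp2",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _build() -> dict[str, str]:
    rng = np.random.default_rng(777)
    lib: dict[str, str] = {}
    for name in _AA3:
        length = int(rng.integers(72, 91))
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        lib[f"tRNA-{name}"] = seq
    return lib


#: name -> sequence; fixed across runs and package versions.
CANONICAL_TRNAS: dict[str, str] = _build()
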