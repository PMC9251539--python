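"""Deterministic seed derivation.

Every stochastic stage draws its seed from the single global run seed through
``derive_seed(master, component, index)``.  The derivation is a pure function
of its arguments (CRC32 of ``"component:index"`` mixed with the master seed),
so split membership, forest initialisation and corpus simulation are all
reproducible from one integer, and no two components share an RNG stream.
"""

from __future__ import annotations

import zlib

_MODULUS = 2**31 - 1


def derive_seed(master: int, component: str, index: int = 0) -> int:
    """Derive a sub-seed for one component repetition.

    Parameters
    ----------
    master : int
        The global run seed.
    component : str
        Name of the consuming stage, e.g. ``"score-split"``.
    index : int
        Repetition index within the stage.

    Returns
    -------
    int
        A seed in ``[0, 2**31 - 1)``, stable across processes and platforms.
    """
    tag = zlib.crc32(f"{component}:{index}".encode("ascii"))
    return (int(master) * 1_000_003 + tag) % _MODULUS
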