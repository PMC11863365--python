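"""Tolerant parsing of shorthand lipid names.

Lipidomics shorthand writes a lipid as a class abbreviation followed by its
acyl-chain composition, e.g. ``PC 15:0-18:1``, ``TG(16:0/18:1/18:2)`` or
``Cer d18:1/16:0``.  Each ``C:D`` token is one chain with ``C`` carbons and
``D`` double bonds; the surrogate-standard matching rule only needs the class
plus the totals summed over chains.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# one acyl/alkyl chain token, with optional sphingoid (d/t) or ether (O-/P-)
# prefixes and an optional isotope-label suffix such as "(d7)"
_CHAIN = re.compile(r"(?:[dtOP]-?)?(\d+):(\d+)")
_CLASS = re.compile(r"^\s*([A-Za-z][A-Za-z0-9]*)")


@dataclass(frozen=True)
class ChainComposition:
    """Class label plus chain totals for one lipid."""

    lipid_class: str
    n_carbons: int
    n_double_bonds: int
    n_chains: int


def parse_lipid_name(name: str) -> ChainComposition:
    """Parse a shorthand lipid name into class and summed chain totals.

    Raises ``ValueError`` when no class token or no chain token is found.
    Isotope-label annotations such as ``(d7)`` are ignored: a ``dN`` token is
    only counted as a chain when it carries a ``C:D`` composition.
    """
    cls = _CLASS.match(name)
    if cls is None:
        raise ValueError(f"cannot find a lipid class token in name {name!r}")
    chains = _CHAIN.findall(name)
    if not chains:
        raise ValueError(f"cannot find any chain 'C:D' token in name {name!r}")
    carbons = sum(int(c) for c, _ in chains)
    doubles = sum(int(d) for _, d in chains)
    return ChainComposition(cls.group(1), carbons, doubles, len(chains))
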