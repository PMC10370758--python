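"""Consensus secondary structures and their helix decomposition.

WUSS (Washington University Secondary Structure) strings from Stockholm
``#=GC SS_cons`` lines are parsed into base-pair sets, and pair sets are
split into helices: maximal runs of stacked pairs in which consecutive pairs
are separated by at most two unpaired residues in total (a 1x1 internal loop
or a 1-2 nucleotide bulge), with at most two on either strand. The helix is
the unit over which per-pair covariation p-values are aggregated.
"""

from __future__ import annotations

import string
from dataclasses import dataclass


class WussParseError(ValueError):
    """Unbalanced or malformed WUSS structure string."""


# bracket layers: nested layers first, then pseudoknot letter layers A..Z/a..z
_OPEN_TO_CLOSE = {"<": ">", "(": ")", "[": "]", "{": "}"}
_CLOSE_TO_OPEN = {v: k for k, v in _OPEN_TO_CLOSE.items()}


@dataclass
class SecondaryStructure:
    """A set of base pairs (i, j), i < j, over 1-based alignment columns."""

    pairs: set[tuple[int, int]]
    length: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i}, {j}) out of range for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"column in more than one pair near ({i}, {j})")
            seen.add(i)
            seen.add(j)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner_map(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass
class Helix:
    """A maximal run of stacked pairs; ``pairs`` has strictly increasing i and
    strictly decreasing j."""

    pairs: list[tuple[int, int]]
    id: int = 0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("helix must contain at least one pair")
        for (i, j), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            if not (i2 > i and j2 < j):
                raise ValueError("helix pairs must nest (increasing i, decreasing j)")
            gi, gj = i2 - i - 1, j - j2 - 1
            if gi > 2 or gj > 2 or gi + gj > 2:
                raise ValueError(
                    f"pairs ({i},{j}) and ({i2},{j2}) violate the <=2-unpaired stacking rule"
                )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def left_start(self) -> int:
        return self.pairs[0][0]

    @property
    def left_end(self) -> int:
        return self.pairs[-1][0]

    @property
    def right_start(self) -> int:
        return self.pairs[-1][1]

    @property
    def right_end(self) -> int:
        return self.pairs[0][1]


def parse_wuss(ss: str) -> SecondaryStructure:
    """Parse a WUSS string into a :class:`SecondaryStructure`.

    Layers ``<>``, ``()``, ``[]``, ``{}`` and pseudoknot letter layers
    ``Aa``..``Zz`` are matched independently by stack; every other character
    is unpaired. Crossing pairs are legal between layers, never within one.
    """
    stacks: dict[str, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for pos0, ch in enumerate(ss):
        pos = pos0 + 1
        if ch in _OPEN_TO_CLOSE:
            stacks.setdefault(ch, []).append(pos)
        elif ch in _CLOSE_TO_OPEN:
            layer = _CLOSE_TO_OPEN[ch]
            stack = stacks.get(layer, [])
            if not stack:
                raise WussParseError(
                    f"unbalanced layer {layer}{_OPEN_TO_CLOSE[layer]!s}: "
                    f"unmatched {ch!r} at position {pos}"
                )
            pairs.add((stack.pop(), pos))
        elif ch in string.ascii_uppercase:
            stacks.setdefault(ch, []).append(pos)
        elif ch in string.ascii_lowercase:
            layer = ch.upper()
            stack = stacks.get(layer, [])
            if not stack:
                raise WussParseError(
                    f"unbalanced pseudoknot layer {layer}: unmatched {ch!r} at position {pos}"
                )
            pairs.add((stack.pop(), pos))
        # every other character (. , _ : - ~ etc.) is unpaired
    for layer, stack in stacks.items():
        if stack:
            raise WussParseError(
                f"unbalanced layer {layer}: unmatched opener at position {stack[-1]}"
            )
    return SecondaryStructure(pairs=pairs, length=len(ss))


def _layer_decomposition(pairs: set[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    """Greedily split pairs into non-crossing layers (first layer maximal)."""
    remaining = sorted(pairs)
    layers: list[set[tuple[int, int]]] = []
    while remaining:
        layer: list[tuple[int, int]] = []
        rest: list[tuple[int, int]] = []
        for p in remaining:
            if all(not _crosses(p, q) for q in layer):
                layer.append(p)
            else:
                rest.append(p)
        layers.append(set(layer))
        remaining = rest
    return layers


def _crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


def pairs_to_wuss(ss: SecondaryStructure) -> str:
    """Render a structure as WUSS: nested layers with ``<>``, each further
    (pseudoknotted) layer with successive letters ``Aa``, ``Bb``, ..."""
    out = ["."] * ss.length
    layers = _layer_decomposition(ss.pairs)
    if len(layers) > 27:
        raise ValueError("more than 26 pseudoknot layers are not representable")
    for n, layer in enumerate(layers):
        if n == 0:
            op, cl = "<", ">"
        else:
            op, cl = string.ascii_uppercase[n - 1], string.ascii_lowercase[n - 1]
        for i, j in layer:
            out[i - 1] = op
            out[j - 1] = cl
    return "".join(out)


def _stackable(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """True if pair b can continue the helix ending at pair a."""
    (i, j), (i2, j2) = a, b
    if not (i2 > i and j2 < j):
        return False
    gi, gj = i2 - i - 1, j - j2 - 1
    return gi <= 2 and gj <= 2 and gi + gj <= 2


def decompose_helices(ss: SecondaryStructure) -> list[Helix]:
    """Split a structure into helices under the <=2-unpaired stacking rule.

    Consecutive pairs (i,j), (i',j') belong to the same helix iff
    i'-i-1 <= 2, j-j'-1 <= 2 and their sum is <= 2 — i.e. a 1x1 internal
    loop or a 1-2 nt bulge is absorbed, anything larger starts a new helix.
    Pairs from different pseudoknot layers never share a helix, and a helix
    is also broken where another helix's strand interleaves. Every pair
    belongs to exactly one helix; helices are ordered by leftmost i.
    """
    helices: list[list[tuple[int, int]]] = []
    for layer in _layer_decomposition(ss.pairs):
        ordered = sorted(layer)
        current: list[tuple[int, int]] = []
        for pair in ordered:
            if current and _stackable(current[-1], pair):
                current.append(pair)
            else:
                if current:
                    helices.append(current)
                current = [pair]
        if current:
            helices.append(current)
    helices.sort(key=lambda h: h[0])
    return [Helix(pairs=h, id=n + 1) for n, h in enumerate(helices)]
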