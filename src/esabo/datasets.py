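"""Built-in example data.

The 15-species benchmark network below (species labelled A through O, ten
synergistic and ten competitive interactions) is the standard worked example
used across the documentation, tests and benchmarks: it is small enough to
enumerate exhaustively yet rich enough to show both clean sign recovery and
the occasional frustrated synergistic edge that scores strongly negative.
"""

from __future__ import annotations

from .simulator import InteractionNetwork

__all__ = ["demo_network", "DEMO_POSITIVE_EDGES", "DEMO_NEGATIVE_EDGES"]

DEMO_POSITIVE_EDGES: tuple[tuple[str, str], ...] = (
    ("H", "M"),
    ("E", "L"),
    ("K", "N"),
    ("D", "H"),
    ("A", "I"),
    ("J", "L"),
    ("B", "O"),
    ("H", "J"),
    ("B", "N"),
    ("F", "H"),
)

DEMO_NEGATIVE_EDGES: tuple[tuple[str, str], ...] = (
    ("A", "O"),
    ("D", "O"),
    ("D", "L"),
    ("F", "M"),
    ("E", "J"),
    ("G", "M"),
    ("B", "G"),
    ("C", "H"),
    ("A", "M"),
    ("L", "M"),
)


def demo_network() -> InteractionNetwork:
    """The 15-species demonstration network (10 synergistic, 10 competitive edges)."""
    labels = tuple("ABCDEFGHIJKLMNO")
    return InteractionNetwork.from_edges(
        labels, DEMO_POSITIVE_EDGES, DEMO_NEGATIVE_EDGES
    )
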