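"""Marker signatures from signed principal-component score rankings.

A cell-type signature is the intersection of top-k protein lists taken from
two (or more) signed component rankings — e.g. the 75 most negative PC1
scores intersected with the 75 most positive PC2 scores characterizes the
fresh fetal phenotype.  Single extreme proteins can also be located by a
primary optimization direction under sign constraints on other components.

Ties at the k-th rank are broken by accession lexicographic order and
logged, since rank ties make top-k membership otherwise ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import NotFoundError

logger = logging.getLogger(__name__)

DIRECTIONS = ("most_negative", "most_positive")

#: Default per-list size.
DEFAULT_K = 75

#: Signature criteria for the three cell types, on oriented components
#: (maturity positive on PC1, fresh-fetal positive on PC2, dedifferentiated
#: culture positive on PC3).
DEFAULT_SIGNATURES = {
    "fresh_fetal": (("PC1", "most_negative"), ("PC2", "most_positive")),
    "hepg2": (("PC1", "most_negative"), ("PC2", "most_negative")),
    "fresh_adult": (("PC1", "most_positive"), ("PC3", "most_negative")),
}


@dataclass
class MarkerSet:
    name: str
    criteria: tuple[tuple[str, str], ...]
    k: int
    table: pd.DataFrame  # index: accession; per-criterion score and rank columns

    @property
    def proteins(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def top_k(scores: pd.Series, direction: str, k: int) -> list[str]:
    """The k proteins ranked by score in the stated direction.

    Ties are broken by accession order; a tie spanning the k-th boundary is
    logged because membership then depends on the tie-break.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if k <= 0:
        raise ValueError("k must be >= 1")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} available proteins")
    ascending = direction == "most_negative"
    # stable sort by (value, accession): sort by accession first, then by value
    frame = scores.rename("score").rename_axis("accession").reset_index()
    frame = frame.sort_values("accession", kind="stable")
    frame = frame.sort_values("score", ascending=ascending, kind="stable")
    if len(scores) > k:
        boundary, first_out = frame["score"].iloc[k - 1], frame["score"].iloc[k]
        if boundary == first_out:
            logger.info("top_k tie at rank %d (score %g); broken by accession order",
                        k, boundary)
    return frame["accession"].head(k).tolist()


def signature(
    scoresets: pd.DataFrame,
    criteria: Sequence[tuple[str, str]],
    k: int = DEFAULT_K,
    name: str = "signature",
) -> MarkerSet:
    """Intersection of the criteria's top-k lists with scores and ranks attached.

    ``scoresets`` is the proteins x components score matrix (oriented).  An
    empty intersection is a valid, empty marker set.
    """
    criteria = tuple((str(c), d) for c, d in criteria)
    for component, direction in criteria:
        if component not in scoresets.columns:
            raise ValueError(f"unknown component {component!r}")
        if direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    lists = {
        (component, direction): top_k(scoresets[component], direction, k)
        for component, direction in criteria
    }
    common: set[str] | None = None
    for members in lists.values():
        common = set(members) if common is None else common & set(members)
    members = sorted(common or set())
    table = pd.DataFrame(index=pd.Index(members, name="accession"))
    for component, direction in criteria:
        ordered = lists[(component, direction)]
        rank = {acc: i + 1 for i, acc in enumerate(ordered)}
        table[f"{component}_score"] = scoresets.loc[members, component]
        table[f"{component}_{direction}_rank"] = [rank[a] for a in members]
    return MarkerSet(name, criteria, k, table)


def extreme_protein(
    scoresets: pd.DataFrame,
    primary: tuple[str, str],
    constraints: Sequence[tuple[str, str]] = (),
) -> str:
    """The protein optimal in the primary direction among those satisfying
    every sign constraint (``(component, "positive"|"negative")``); ties by
    accession order."""
    component, direction = primary
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    eligible = scoresets
    for c, sign in constraints:
        if sign not in ("positive", "negative"):
            raise ValueError(f"constraint sign must be 'positive' or 'negative', got {sign!r}")
        col = eligible[c]
        eligible = eligible.loc[col > 0] if sign == "positive" else eligible.loc[col < 0]
    if eligible.empty:
        raise NotFoundError(f"no protein satisfies constraints {list(constraints)}")
    ascending = direction == "most_negative"
    frame = eligible[[component]].rename_axis("accession").reset_index()
    frame = frame.sort_values("accession", kind="stable")
    frame = frame.sort_values(component, ascending=ascending, kind="stable")
    return str(frame["accession"].iloc[0])


def write_marker_set(ms: MarkerSet, path) -> None:
    out = ms.table.copy()
    out.insert(0, "accession", out.index)
    out.to_csv(path, sep="\t", index=False)
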