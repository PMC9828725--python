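"""Food-web ingestion, validation, exclusion rules and degree sequences.

A food web is a directed trophic graph: a link (r, c) means species c
consumes species r.  Adjacency matrices follow the GlobalWeb/EcoBase
convention: rows are resources, columns are consumers, a strictly positive
cell is a link.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

ECOSYSTEMS = ("coastal", "freshwater", "marine", "terrestrial", "unknown")

EXCLUSION_REASONS = ("non_numerical_entry", "duplicated_species", "missing_location")


class MalformedTableError(ValueError):
    """The adjacency table cannot be interpreted at all (non-square,
    row/column label mismatch).  Distinct from a rule-based rejection,
    which is data, not an error."""


@dataclass(frozen=True)
class Rejection:
    """A web excluded by one of the dataset filtering rules."""

    web_id: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason: {self.reason}")


@dataclass
class FoodWeb:
    """Directed trophic graph with per-web metadata.

    Parameters
    ----------
    id : str
        Web identifier.
    species : sequence of str
        Ordered, unique species labels.  Order is preserved through
        ``degree_sequence``.
    links : set of (str, str)
        Directed resource -> consumer pairs.  Self-loops (cannibalism) are
        dropped at construction: they are inconsistently recorded across
        sources and distort the degree distribution.
    ecosystem : str
        One of coastal / freshwater / marine / terrestrial / unknown.
    location : (float, float) or None
        (lat, lon) in decimal degrees.
    disturbance : float or None
        Pre-extracted human-pressure covariate, scaled to [0, 1].
    """

    id: str
    species: tuple
    links: frozenset
    ecosystem: str = "unknown"
    location: Optional[tuple] = None
    disturbance: Optional[float] = None

    def __init__(
        self,
        id: str,
        species: Sequence[str],
        links: Iterable[tuple],
        ecosystem: str = "unknown",
        location: Optional[tuple] = None,
        disturbance: Optional[float] = None,
    ) -> None:
        species = tuple(species)
        if len(set(species)) != len(species):
            raise ValueError(f"web {id!r}: duplicate species labels")
        known = set(species)
        cleaned = set()
        for r, c in links:
            if r not in known or c not in known:
                raise ValueError(f"web {id!r}: link ({r!r}, {c!r}) references unknown label")
            if r != c:  # drop self-loops
                cleaned.add((r, c))
        self.id = id
        self.species = species
        self.links = frozenset(cleaned)
        if ecosystem not in ECOSYSTEMS:
            raise ValueError(f"web {id!r}: unknown ecosystem {ecosystem!r}")
        self.ecosystem = ecosystem
        self.location = tuple(location) if location is not None else None
        self.disturbance = disturbance

    # -- derived structure -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def resources_of(self, sp: str) -> set:
        """Species consumed by `sp` (its prey)."""
        return {r for r, c in self.links if c == sp}

    def basal_species(self) -> set:
        """Species with no resources (primary producers)."""
        consumers = {c for _, c in self.links}
        return set(self.species) - consumers

    def subweb(self, keep: Iterable[str]) -> "FoodWeb":
        keep = set(keep)
        return FoodWeb(
            id=self.id,
            species=tuple(s for s in self.species if s in keep),
            links={(r, c) for r, c in self.links if r in keep and c in keep},
            ecosystem=self.ecosystem,
            location=self.location,
            disturbance=self.disturbance,
        )


@dataclass
class ExclusionReport:
    kept: list = field(default_factory=list)
    excluded: list = field(default_factory=list)  # list of Rejection

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": i, "status": "kept", "reason": ""} for i in self.kept]
        rows += [
            {"id": r.web_id, "status": "excluded", "reason": r.reason}
            for r in self.excluded
        ]
        return pd.DataFrame(rows, columns=["id", "status", "reason"])


# ---------------------------------------------------------------------------
# ingestion


def read_adjacency_matrix(
    text: "str | io.TextIOBase",
    id: str,
    *,
    link_threshold: float = 0.0,
    ecosystem: str = "unknown",
    location: Optional[tuple] = None,
    disturbance: Optional[float] = None,
):
    """Parse a square labelled adjacency table into a FoodWeb.

    Rows are resources, columns consumers; any cell strictly greater than
    ``link_threshold`` is a link (EcoBase matrices carry flows, GlobalWeb
    0/1).  Returns a :class:`FoodWeb` or, when a dataset exclusion rule
    fires (non-numerical cell, duplicated species label), a
    :class:`Rejection` — rejections are data, not errors.

    Raises
    ------
    MalformedTableError
        Table is not square or row and column label sets differ.
    """
    if isinstance(text, str):
        text = io.StringIO(text)
    dialect_rows = list(csv.reader(text, delimiter=_sniff_delimiter(text)))
    rows = [r for r in dialect_rows if any(cell.strip() for cell in r)]
    if len(rows) < 2:
        raise MalformedTableError(f"web {id!r}: table too small")
    col_labels = [c.strip() for c in rows[0][1:]]
    row_labels = [r[0].strip() for r in rows[1:]]
    body = [r[1:] for r in rows[1:]]
    if any(len(b) != len(col_labels) for b in body) or len(row_labels) != len(col_labels):
        raise MalformedTableError(f"web {id!r}: table is not square")
    if sorted(row_labels) != sorted(col_labels):
        raise MalformedTableError(f"web {id!r}: row/column label sets differ")

    if len(set(row_labels)) != len(row_labels):
        return Rejection(id, "duplicated_species")

    links = set()
    for r_lab, brow in zip(row_labels, body):
        for c_lab, cell in zip(col_labels, brow):
            cell = cell.strip()
            if cell == "":
                cell = "0"
            try:
                val = float(cell)
            except ValueError:
                return Rejection(id, "non_numerical_entry")
            if not math.isfinite(val):
                return Rejection(id, "non_numerical_entry")
            if val > link_threshold:
                links.add((r_lab, c_lab))
    return FoodWeb(
        id=id,
        species=row_labels,
        links=links,
        ecosystem=ecosystem,
        location=location,
        disturbance=disturbance,
    )


def _sniff_delimiter(stream: io.TextIOBase) -> str:
    head = stream.read(4096)
    stream.seek(0)
    return "\t" if head.count("\t") > head.count(",") else ","


def write_edge_list(web: FoodWeb, stream: io.TextIOBase) -> None:
    """Canonical TSV edge list (resource, consumer), sorted."""
    stream.write("resource\tconsumer\n")
    for r, c in sorted(web.links):
        stream.write(f"{r}\t{c}\n")


def read_edge_list(stream: "str | io.TextIOBase", id: str, **meta) -> FoodWeb:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t")
    links = set(zip(df["resource"].astype(str), df["consumer"].astype(str)))
    species = sorted({s for pair in links for s in pair})
    return FoodWeb(id=id, species=species, links=links, **meta)


# ---------------------------------------------------------------------------
# exclusion rules


def apply_exclusion_rules(entries: Sequence) -> tuple:
    """Apply the dataset filtering rules to a list of ingested webs.

    ``entries`` holds :class:`FoodWeb` and :class:`Rejection` objects as
    produced by :func:`read_adjacency_matrix`.  A FoodWeb lacking a usable
    geographical location is excluded with reason ``missing_location``.

    Returns (kept webs, :class:`ExclusionReport`).  Idempotent: running the
    rules on the kept set again keeps everything.
    """
    kept, report = [], ExclusionReport()
    for entry in entries:
        if isinstance(entry, Rejection):
            report.excluded.append(entry)
            continue
        if entry.location is None or any(
            v is None or not math.isfinite(float(v)) for v in entry.location
        ):
            report.excluded.append(Rejection(entry.id, "missing_location"))
            continue
        kept.append(entry)
        report.kept.append(entry.id)
    return kept, report


# ---------------------------------------------------------------------------
# degrees


def degree_sequence(
    web: FoodWeb, convention: Literal["undirected", "total_directed"] = "undirected"
) -> list:
    """Per-species degree, in species order.

    The default convention collapses the directed graph: a species' degree
    is the number of *distinct other* species it is linked to in either
    direction, so a mutually-predating pair contributes one to each.  The
    ``total_directed`` switch counts in- plus out-links instead.
    """
    if web.n_species == 0:
        raise ValueError("empty web has no degree sequence")
    if convention == "undirected":
        neighbours = {s: set() for s in web.species}
        for r, c in web.links:
            neighbours[r].add(c)
            neighbours[c].add(r)
        return [len(neighbours[s]) for s in web.species]
    elif convention == "total_directed":
        deg = {s: 0 for s in web.species}
        for r, c in web.links:
            deg[r] += 1
            deg[c] += 1
        return [deg[s] for s in web.species]
    raise ValueError(f"unknown degree convention {convention!r}")


def adjacency_arrays(web: FoodWeb):
    """Boolean (directed, undirected) adjacency matrices in species order.

    ``directed[i, j]`` is True when species j consumes species i.
    """
    n = web.n_species
    index = {s: i for i, s in enumerate(web.species)}
    directed = np.zeros((n, n), dtype=bool)
    for r, c in web.links:
        directed[index[r], index[c]] = True
    undirected = directed | directed.T
    return directed, undirected


def read_metadata(stream: "str | io.TextIOBase") -> pd.DataFrame:
    """Metadata CSV with columns id, ecosystem, lat, lon, disturbance."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream)
    required = {"id", "ecosystem", "lat", "lon", "disturbance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    df["id"] = df["id"].astype(str)
    return df
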