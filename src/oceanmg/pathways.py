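"""Marker-KO pathway abundance and completeness logic for nitrogen assimilation
and amino-acid biosynthesis.

The route database is a declarative description of

* generic nitrogen-assimilation routes (ordered steps, each an OR-set of
  enzymes: a route is usable when every step has at least one present member),
* nitrogen-cycle modules (a module is detected when any of its marker enzymes
  is present),
* de novo amino-acid biosynthesis pathways as AND-of-OR step lists, with
  bidirectional conversion edges (e.g. serine <-> glycine via *glyA*) and
  per-amino-acid transporter fallbacks that can compensate a broken pathway
  by uptake from the environment.

Enzyme ids are gene symbols (*gdhA*, *nirA*, *nifH*, ...); an editable KO-alias
column travels with the database but carries no logic.  A copy of the database
curated for oligotrophic surface-water communities (including the observed
enzyme sets of a *Prochlorococcus*-dominated metagenome) ships with the
package and is returned by :func:`load_routedb`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PathwayDef",
    "AAStatus",
    "RouteDB",
    "load_routedb",
    "pathway_abundance",
    "enumerate_routes",
    "module_presence",
    "aa_gap_analysis",
    "table1_enzyme_pattern",
]

COMPLETE = "complete"
INCOMPLETE = "incomplete"
INCOMPLETE_WITH_UPTAKE = "incomplete_with_uptake"


@dataclass(frozen=True)
class PathwayDef:
    """A pathway quantified by the mean relative abundance of its marker KOs."""

    pathway_id: str
    marker_kos: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_kos", frozenset(self.marker_kos))
        if not self.marker_kos:
            raise ValueError(f"pathway {self.pathway_id!r} has an empty marker set")


@dataclass(frozen=True)
class AAStatus:
    """Completeness call for one amino acid's de novo biosynthesis pathway.

    ``uptake`` records how an incomplete pathway can be compensated:
    ``"transporter"`` for a direct importer of the amino acid itself, or
    ``"conversion:<aa>:<enzyme>"`` when the amino acid is reachable from an
    importable partner through a present bidirectional conversion enzyme.
    """

    amino_acid: str
    status: str
    missing_steps: tuple[str, ...] = ()
    uptake: str | None = None

    def __post_init__(self) -> None:
        if (self.status == COMPLETE) != (len(self.missing_steps) == 0):
            raise ValueError("complete status must coincide with no missing steps")
        if self.status == INCOMPLETE_WITH_UPTAKE and self.uptake is None:
            raise ValueError("incomplete_with_uptake requires an uptake mechanism")


def _steps(raw: Sequence[Sequence[str]]) -> tuple[frozenset[str], ...]:
    return tuple(frozenset(s) for s in raw)


@dataclass
class RouteDB:
    """Declarative pathway database; see module docstring for semantics."""

    vocabulary: dict[str, str | None]
    transporter_vocabulary: dict[str, str | None]
    routes: dict[str, tuple[frozenset[str], ...]]
    modules: dict[str, frozenset[str]]
    aa_pathways: dict[str, tuple[frozenset[str], ...]]
    conversions: list[tuple[str, str, str]]
    transporters: dict[str, frozenset[str]]
    observed_sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vocab = set(self.vocabulary)
        referenced = set()
        for steps in self.routes.values():
            referenced.update(*steps)
        for markers in self.modules.values():
            referenced.update(markers)
        for steps in self.aa_pathways.values():
            referenced.update(*steps)
        referenced.update(enz for _, _, enz in self.conversions)
        unknown = referenced - vocab
        if unknown:
            raise ValueError(f"enzyme ids missing from vocabulary: {sorted(unknown)}")
        t_unknown = {
            t for ts in self.transporters.values() for t in ts
        } - set(self.transporter_vocabulary)
        if t_unknown:
            raise ValueError(f"transporter ids missing from vocabulary: {sorted(t_unknown)}")

    # -- (de)serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "RouteDB":
        return cls(
            vocabulary=dict(d["vocabulary"]),
            transporter_vocabulary=dict(d["transporter_vocabulary"]),
            routes={rid: _steps(steps) for rid, steps in d["routes"].items()},
            modules={mid: frozenset(m) for mid, m in d["modules"].items()},
            aa_pathways={aa: _steps(steps) for aa, steps in d["aa_pathways"].items()},
            conversions=[tuple(edge) for edge in d["conversions"]],
            transporters={aa: frozenset(t) for aa, t in d.get("transporters", {}).items()},
            observed_sets={k: frozenset(v) for k, v in d.get("observed_sets", {}).items()},
        )

    def to_dict(self) -> dict:
        return {
            "vocabulary": dict(self.vocabulary),
            "transporter_vocabulary": dict(self.transporter_vocabulary),
            "routes": {rid: [sorted(s) for s in steps] for rid, steps in self.routes.items()},
            "modules": {mid: sorted(m) for mid, m in self.modules.items()},
            "aa_pathways": {aa: [sorted(s) for s in steps] for aa, steps in self.aa_pathways.items()},
            "conversions": [list(e) for e in self.conversions],
            "transporters": {aa: sorted(t) for aa, t in self.transporters.items()},
            "observed_sets": {k: sorted(v) for k, v in self.observed_sets.items()},
        }

    def validate_enzymes(self, ids: Iterable[str]) -> frozenset[str]:
        ids = frozenset(ids)
        unknown = ids - set(self.vocabulary)
        if unknown:
            raise ValueError(f"unknown enzyme id(s): {sorted(unknown)}")
        return ids

    def validate_transporters(self, ids: Iterable[str]) -> frozenset[str]:
        ids = frozenset(ids)
        unknown = ids - set(self.transporter_vocabulary)
        if unknown:
            raise ValueError(f"unknown transporter id(s): {sorted(unknown)}")
        return ids


def load_routedb(path: str | None = None) -> RouteDB:
    """Load a route database from JSON; default is the curated copy shipped
    with the package."""
    if path is None:
        text = resources.files("oceanmg").joinpath("data/routes.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return RouteDB.from_dict(json.loads(text))


def table1_enzyme_pattern(db: RouteDB) -> tuple[frozenset[str], frozenset[str]]:
    """Reconstruct the observed *Prochlorococcus* amino-acid enzyme pattern
    from the database's curated observation sets: every amino-acid pathway
    enzyme is present except the recorded absentees, and the recorded
    transporters are present.  Returns ``(present_enzymes, transporters)``."""
    aa_enzymes = {e for steps in db.aa_pathways.values() for step in steps for e in step}
    present = frozenset(aa_enzymes - db.observed_sets["table1_absent_enzymes"])
    return present, db.observed_sets["table1_transporters"]


def pathway_abundance(ko_prof: pd.DataFrame, pathway: PathwayDef) -> pd.Series:
    """Per-sample pathway abundance: total abundance of the marker KOs divided
    by the number of marker KOs (absent markers count as zero).

    ``ko_prof`` is a KO x sample relative-abundance table.
    """
    markers = sorted(pathway.marker_kos)
    sub = ko_prof.reindex(markers).fillna(0.0)
    return sub.sum(axis=0) / len(markers)


def _satisfied(steps: Sequence[frozenset[str]], present: frozenset[str]) -> list[frozenset[str]]:
    """Return the steps with no present member (empty list = complete)."""
    return [step for step in steps if not (step & present)]


def enumerate_routes(present: Iterable[str], db: RouteDB) -> list[str]:
    """List nitrogen-assimilation routes fully usable given a present enzyme
    set, in database order.  A route is usable when every step has at least
    one present member enzyme."""
    present = db.validate_enzymes(present)
    return [rid for rid, steps in db.routes.items() if not _satisfied(steps, present)]


def module_presence(present: Iterable[str], db: RouteDB) -> dict[str, bool]:
    """Presence/absence of each nitrogen-cycle module: a module is detected
    when any of its marker enzymes is present."""
    present = db.validate_enzymes(present)
    return {mid: bool(markers & present) for mid, markers in db.modules.items()}


def aa_gap_analysis(
    present: Iterable[str],
    transporters_present: Iterable[str],
    db: RouteDB,
) -> list[AAStatus]:
    """Gap analysis of de novo amino-acid biosynthesis.

    For each amino acid in the database, every step (OR-set of enzymes) must
    have a present member for the pathway to be complete.  An incomplete
    pathway is downgraded to ``incomplete_with_uptake`` when the organism can
    source the amino acid from the environment, either by a direct transporter
    or through a present bidirectional conversion enzyme linking it to an
    importable partner amino acid.
    """
    present = db.validate_enzymes(present)
    transporters_present = db.validate_transporters(transporters_present)

    def importable(aa: str) -> bool:
        return bool(db.transporters.get(aa, frozenset()) & transporters_present)

    results: list[AAStatus] = []
    for aa, steps in db.aa_pathways.items():
        missing = _satisfied(steps, present)
        if not missing:
            results.append(AAStatus(aa, COMPLETE))
            continue
        missing_labels = tuple("|".join(sorted(step)) for step in missing)
        if importable(aa):
            results.append(AAStatus(aa, INCOMPLETE_WITH_UPTAKE, missing_labels, "transporter"))
            continue
        uptake = None
        for a, b, enz in db.conversions:
            if enz not in present:
                continue
            other = b if a == aa else a if b == aa else None
            if other is not None and importable(other):
                uptake = f"conversion:{other}:{enz}"
                break
        if uptake is not None:
            results.append(AAStatus(aa, INCOMPLETE_WITH_UPTAKE, missing_labels, uptake))
        else:
            results.append(AAStatus(aa, INCOMPLETE, missing_labels))
    return results
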