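"""MedDRA-style PT/HLT/SMQ hierarchy with three-level query expansion.

The dictionary dialect is a project-defined set of four UTF-8 CSV files in
one directory (real MedDRA distributions are licensed and are not read):

- ``pt.csv``            -- ``pt_code,pt_name,hlt_code``
- ``hlt.csv``           -- ``hlt_code,hlt_name``
- ``smq.csv``           -- ``smq_code,smq_name,pt_code,scope`` (one row per
  member PT; ``scope`` is ``narrow`` or ``broad``)
- ``smq_children.csv``  -- ``parent_code,child_code`` (optional file; links a
  comprehensive SMQ to its child SMQs)

Every PT belongs to exactly one HLT; SMQ membership is many-to-many over
PTs. Codes are opaque, case-sensitive identifiers; names are labels only
(distinct SMQs may legitimately share a display name).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from ._common import IntegrityError, ParseError, TermLookupError, logger

SCOPES = ("narrow", "broad")
LEVELS = ("pt", "hlt", "smq")


@dataclass(frozen=True)
class PTTerm:
    """A preferred term: the most specific coding level for one event."""

    pt_code: str
    pt_name: str
    hlt_code: str


@dataclass(frozen=True)
class HLTTerm:
    """A high-level term grouping clinically related PTs."""

    hlt_code: str
    hlt_name: str


@dataclass(frozen=True)
class SMQDef:
    """A standardized query: a curated PT set with per-member scope."""

    smq_code: str
    smq_name: str
    #: pt_code -> "narrow" | "broad"
    members: dict[str, str] = field(default_factory=dict)

    def member_codes(self, scope: str = "combined") -> frozenset[str]:
        if scope == "combined":
            return frozenset(self.members)
        if scope == "narrow":
            return frozenset(c for c, s in self.members.items() if s == "narrow")
        raise ValueError(f"scope must be 'narrow' or 'combined', got {scope!r}")


@dataclass
class MedDRADict:
    """The full hierarchy plus optional comprehensive-SMQ grouping."""

    pts: dict[str, PTTerm]
    hlts: dict[str, HLTTerm]
    smqs: dict[str, SMQDef]
    #: parent smq_code -> list of child smq_codes
    children: dict[str, list[str]] = field(default_factory=dict)

    def pts_under_hlt(self, hlt_code: str) -> frozenset[str]:
        if hlt_code not in self.hlts:
            raise TermLookupError("hlt", hlt_code)
        return frozenset(p.pt_code for p in self.pts.values() if p.hlt_code == hlt_code)

    def codes_at_level(self, level: str) -> list[str]:
        if level == "pt":
            return sorted(self.pts)
        if level == "hlt":
            return sorted(self.hlts)
        if level == "smq":
            return sorted(self.smqs)
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")

    def name_of(self, level: str, code: str) -> str:
        if level == "pt":
            if code not in self.pts:
                raise TermLookupError("pt", code)
            return self.pts[code].pt_name
        if level == "hlt":
            if code not in self.hlts:
                raise TermLookupError("hlt", code)
            return self.hlts[code].hlt_name
        if level == "smq":
            if code not in self.smqs:
                raise TermLookupError("smq", code)
            return self.smqs[code].smq_name
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")


def _read_rows(path: Path, columns: tuple[str, ...]) -> list[tuple[int, dict[str, str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != list(columns):
            raise ParseError(
                f"{path.name}: expected header {','.join(columns)}, "
                f"got {reader.fieldnames}"
            )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if None in row or None in row.values():
                raise ParseError(f"{path.name}: wrong field count", line=lineno)
            if any(not v.strip() for v in row.values()):
                raise ParseError(f"{path.name}: empty or missing field", line=lineno)
            rows.append((lineno, {k: v.strip() for k, v in row.items()}))
    return rows


def load_dictionary(path: str | Path) -> MedDRADict:
    """Load and validate the four-file dictionary dialect from a directory.

    Raises :class:`ParseError` for malformed rows (with line number) and
    :class:`IntegrityError` for duplicate or dangling codes.
    """
    d = Path(path)
    pts: dict[str, PTTerm] = {}
    hlts: dict[str, HLTTerm] = {}
    smqs: dict[str, SMQDef] = {}
    children: dict[str, list[str]] = {}

    for lineno, row in _read_rows(d / "hlt.csv", ("hlt_code", "hlt_name")):
        if row["hlt_code"] in hlts:
            raise IntegrityError(f"hlt.csv line {lineno}: duplicate hlt_code {row['hlt_code']!r}")
        hlts[row["hlt_code"]] = HLTTerm(row["hlt_code"], row["hlt_name"])

    for lineno, row in _read_rows(d / "pt.csv", ("pt_code", "pt_name", "hlt_code")):
        if row["pt_code"] in pts:
            raise IntegrityError(f"pt.csv line {lineno}: duplicate pt_code {row['pt_code']!r}")
        if row["hlt_code"] not in hlts:
            raise IntegrityError(
                f"pt.csv line {lineno}: pt_code {row['pt_code']!r} references "
                f"unknown hlt_code {row['hlt_code']!r}"
            )
        pts[row["pt_code"]] = PTTerm(row["pt_code"], row["pt_name"], row["hlt_code"])

    members: dict[str, dict[str, str]] = {}
    names: dict[str, str] = {}
    for lineno, row in _read_rows(d / "smq.csv", ("smq_code", "smq_name", "pt_code", "scope")):
        code = row["smq_code"]
        if row["scope"] not in SCOPES:
            raise ParseError(f"smq.csv: scope must be narrow|broad, got {row['scope']!r}", line=lineno)
        if row["pt_code"] not in pts:
            raise IntegrityError(
                f"smq.csv line {lineno}: SMQ {code!r} references unknown pt_code {row['pt_code']!r}"
            )
        if code in names and names[code] != row["smq_name"]:
            raise IntegrityError(f"smq.csv line {lineno}: SMQ {code!r} has conflicting names")
        if row["pt_code"] in members.get(code, {}):
            raise IntegrityError(
                f"smq.csv line {lineno}: duplicate member {row['pt_code']!r} in SMQ {code!r}"
            )
        names[code] = row["smq_name"]
        members.setdefault(code, {})[row["pt_code"]] = row["scope"]
    for code, mem in members.items():
        smqs[code] = SMQDef(code, names[code], mem)

    child_file = d / "smq_children.csv"
    if child_file.exists():
        for lineno, row in _read_rows(child_file, ("parent_code", "child_code")):
            parent, child = row["parent_code"], row["child_code"]
            if child not in smqs:
                raise IntegrityError(
                    f"smq_children.csv line {lineno}: unknown child SMQ {child!r}"
                )
            if parent not in smqs:
                # A pure grouping SMQ: a comprehensive query may have no
                # direct members of its own.
                smqs[parent] = SMQDef(parent, parent, {})
            children.setdefault(parent, []).append(child)
        # reject cycles with a simple depth-bounded walk
        for parent in children:
            seen = {parent}
            stack = list(children[parent])
            while stack:
                c = stack.pop()
                if c in seen:
                    raise IntegrityError(f"SMQ child cycle involving {c!r}")
                seen.add(c)
                stack.extend(children.get(c, []))

    logger.debug("loaded dictionary: %d PTs, %d HLTs, %d SMQs", len(pts), len(hlts), len(smqs))
    return MedDRADict(pts=pts, hlts=hlts, smqs=smqs, children=children)


def expand_query(
    d: MedDRADict, level: str, code: str, scope: str = "combined"
) -> frozenset[str]:
    """Expand a code at one of the three hierarchy levels to its PT set.

    PT level returns a singleton; HLT level all PTs under the HLT; SMQ level
    the member PTs filtered by ``scope`` ("narrow" keeps narrow-scoped
    members only, "combined" keeps all), with a comprehensive SMQ expanding
    through its children by set union. The default scope is ``combined`` —
    the maximal-sensitivity reading used for comprehensive liver-injury
    searches.
    """
    if level == "pt":
        if code not in d.pts:
            raise TermLookupError("pt", code)
        return frozenset({code})
    if level == "hlt":
        return d.pts_under_hlt(code)
    if level == "smq":
        if code not in d.smqs:
            raise TermLookupError("smq", code)
        out = set(d.smqs[code].member_codes(scope))
        for child in d.children.get(code, []):
            out |= expand_query(d, "smq", child, scope)
        return frozenset(out)
    raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
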