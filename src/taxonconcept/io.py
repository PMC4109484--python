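"""Readers and writers for checklists, mappings and the concept-tree store.

Checklists are comma-delimited UTF-8 text with a Darwin Core Taxon header
(``taxonID, scientificName, taxonRank, parentNameUsageID, vernacularName``)
and leading ``# key: value`` comment lines carrying the checklist metadata
(authority, version, year, scope).  Mappings use the same conventions.  The
tree store is a YAML document, schema-validated on load with error messages
that name the offending paths.  All writers order their output so that equal
inputs produce byte-identical files.
"""

from __future__ import annotations

import csv
import io as _io
import os
import re
from pathlib import Path
from typing import Union

import yaml

from .errors import ChecklistParseError, StoreSchemaError
from .mapper import (Checklist, GLOBAL_SCOPE, MappingEntry, MappingResult,
                     MappingStatus, TaxonRecord)
from .store import (ConceptStore, Kind, NameType, NameUsage, Rank,
                    SynonymEntry, TreeSet, TreeVariant, is_concept_id)

__all__ = [
    "read_checklist", "write_checklist",
    "read_mapping", "write_mapping",
    "load_store", "save_store",
    "read_scope", "write_scope",
]

CHECKLIST_COLUMNS = ("taxonID", "scientificName", "taxonRank",
                     "parentNameUsageID", "vernacularName")
MAPPING_COLUMNS = ("taxonID", "scientificName", "status", "conceptID",
                   "candidates", "variant")

_META_RE = re.compile(r"^#\s*([A-Za-z_][A-Za-z_ ]*?)\s*:\s*(.*?)\s*$")


# ---------------------------------------------------------------------------
# checklists


def _parse_scope(text: str):
    text = text.strip()
    if not text or text.lower() == GLOBAL_SCOPE:
        return GLOBAL_SCOPE
    return frozenset(p.strip() for p in text.split(";") if p.strip())


def read_checklist(path: Union[str, os.PathLike]) -> Checklist:
    """Parse a Darwin Core checklist file into a validated :class:`Checklist`;
    row order is preserved."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    meta: dict[str, str] = {}
    body: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            m = _META_RE.match(line)
            if m:
                meta[m.group(1).strip().lower()] = m.group(2)
        elif line.strip():
            body.append((lineno, line))
    if not body:
        raise ChecklistParseError("no header row found")

    rows = list(csv.reader([text for _, text in body]))
    header = [h.strip() for h in rows[0]]
    for col in ("taxonID", "scientificName", "taxonRank"):
        if col not in header:
            raise ChecklistParseError(f"missing required column {col!r}",
                                      line=body[0][0])
    col = {name: header.index(name) for name in header}

    records: list[TaxonRecord] = []
    seen: set[str] = set()
    for (lineno, _), cells in zip(body[1:], rows[1:]):
        if not any(c.strip() for c in cells):
            continue
        if len(cells) < len(header):
            cells = cells + [""] * (len(header) - len(cells))

        def get(name: str) -> str:
            i = col.get(name)
            return cells[i].strip() if i is not None else ""

        tid = get("taxonID")
        if not tid:
            raise ChecklistParseError("empty taxonID", line=lineno)
        if tid in seen:
            raise ChecklistParseError(f"duplicate taxonID {tid!r}", line=lineno)
        seen.add(tid)
        try:
            rank = Rank(get("taxonRank").lower())
        except ValueError:
            raise ChecklistParseError(
                f"taxonRank must be one of "
                f"{[r.value for r in Rank]}, got {get('taxonRank')!r}",
                line=lineno) from None
        records.append(TaxonRecord(
            taxon_id=tid,
            scientific_name=get("scientificName"),
            rank=rank,
            parent_taxon_id=get("parentNameUsageID") or None,
            vernacular=get("vernacularName") or None,
        ))
    for r in records:
        if r.parent_taxon_id is not None and r.parent_taxon_id not in seen:
            raise ChecklistParseError(
                f"record {r.taxon_id} references missing parent "
                f"{r.parent_taxon_id}")
    try:
        year = int(meta.get("year", "0"))
    except ValueError:
        raise ChecklistParseError(f"year must be an integer, got "
                                  f"{meta['year']!r}") from None
    return Checklist(
        authority=meta.get("authority", ""),
        version_label=meta.get("version", ""),
        year=year,
        records=records,
        scope=_parse_scope(meta.get("scope", GLOBAL_SCOPE)),
    )


def write_checklist(checklist: Checklist, path: Union[str, os.PathLike]) -> None:
    buf = _io.StringIO()
    scope = GLOBAL_SCOPE if checklist.scope == GLOBAL_SCOPE \
        else ";".join(sorted(checklist.scope))
    buf.write(f"# authority: {checklist.authority}\n")
    buf.write(f"# version: {checklist.version_label}\n")
    buf.write(f"# year: {checklist.year}\n")
    buf.write(f"# scope: {scope}\n")
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(CHECKLIST_COLUMNS)
    for r in checklist.records:
        w.writerow([r.taxon_id, r.scientific_name, r.rank.value,
                    r.parent_taxon_id or "", r.vernacular or ""])
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# mappings


def write_mapping(result: MappingResult, path: Union[str, os.PathLike]) -> None:
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(MAPPING_COLUMNS)
    for e in result:
        w.writerow([
            e.taxon_id, e.scientific_name, e.status.value, e.concept or "",
            ";".join(e.candidates),
            "" if e.variant is None else str(e.variant),
        ])
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_mapping(path: Union[str, os.PathLike]) -> MappingResult:
    lines = [l for l in Path(path).read_text(encoding="utf-8").splitlines()
             if l.strip() and not l.startswith("#")]
    rows = list(csv.reader(lines))
    if not rows or [h.strip() for h in rows[0]] != list(MAPPING_COLUMNS):
        raise ChecklistParseError(
            f"mapping file must start with header {','.join(MAPPING_COLUMNS)}")
    entries = []
    for cells in rows[1:]:
        tid, name, status, concept, cand, variant = (cells + [""] * 6)[:6]
        entries.append(MappingEntry(
            taxon_id=tid,
            scientific_name=name,
            status=MappingStatus(status),
            concept=concept or None,
            candidates=tuple(c for c in cand.split(";") if c),
            variant=int(variant) if variant else None,
        ))
    return MappingResult(entries)


# ---------------------------------------------------------------------------
# the tree store


def save_store(store: ConceptStore, path: Union[str, os.PathLike]) -> None:
    doc = {
        "concepts": {
            cid: {
                "kind": node.kind.value,
                "names": [{"name": u.name, "rank": u.rank.value}
                          for u in node.names],
            }
            for cid, node in sorted(store.concepts.items())
        },
        "treesets": [
            {
                "root": ts.root,
                "variants": [
                    {p: sorted(cs) for p, cs in sorted(v.edges.items())}
                    for v in ts.variants
                ],
            }
            for ts in sorted(store.treesets, key=lambda t: t.root)
        ],
        "synonyms": [
            {"name": s.name, "concept": s.concept, "type": s.name_type.value,
             **({"language": s.language} if s.language else {})}
            for s in sorted(store.synonyms,
                            key=lambda s: (s.name, s.concept, s.name_type.value))
        ],
        "hybrids": {cid: sorted(ps) for cid, ps in sorted(store.hybrids.items())},
    }
    text = yaml.safe_dump(doc, sort_keys=True, allow_unicode=True,
                          default_flow_style=False)
    tmp = Path(str(path) + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def _expect(value, types, where: str, problems: list[str]) -> bool:
    if not isinstance(value, types):
        tn = types.__name__ if isinstance(types, type) \
            else "/".join(t.__name__ for t in types)
        problems.append(f"{where}: expected {tn}, got {type(value).__name__}")
        return False
    return True


def load_store(path: Union[str, os.PathLike]) -> ConceptStore:
    """Load and schema-validate a store document; raises
    :class:`StoreSchemaError` listing every offending path."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if doc is None:
        doc = {}
    problems: list[str] = []
    if not _expect(doc, dict, "document", problems):
        raise StoreSchemaError(problems)
    unknown = set(doc) - {"concepts", "treesets", "synonyms", "hybrids"}
    for key in sorted(unknown):
        problems.append(f"document: unknown section {key!r}")

    store = ConceptStore()
    concepts = doc.get("concepts") or {}
    if _expect(concepts, dict, "concepts", problems):
        for cid, spec in sorted(concepts.items()):
            where = f"concepts/{cid}"
            if not is_concept_id(cid):
                problems.append(f"{where}: not a 16-hex-character identifier")
                continue
            spec = spec or {}
            if not _expect(spec, dict, where, problems):
                continue
            try:
                kind = Kind(spec.get("kind", "species"))
            except ValueError:
                problems.append(f"{where}/kind: invalid kind {spec.get('kind')!r}")
                kind = Kind.OTHER
            names = []
            for i, u in enumerate(spec.get("names") or []):
                uw = f"{where}/names/{i}"
                if not _expect(u, dict, uw, problems):
                    continue
                try:
                    rank = Rank(u.get("rank", "species"))
                except ValueError:
                    problems.append(f"{uw}/rank: invalid rank {u.get('rank')!r}")
                    continue
                if not _expect(u.get("name"), str, f"{uw}/name", problems):
                    continue
                names.append(NameUsage(u["name"], rank))
            store.add_concept(cid, kind, names)

    claimed: dict[str, int] = {}
    treesets = doc.get("treesets") or []
    if _expect(treesets, list, "treesets", problems):
        for ti, tspec in enumerate(treesets):
            where = f"treesets/{ti}"
            if not _expect(tspec, dict, where, problems):
                continue
            root = tspec.get("root")
            if not is_concept_id(root):
                problems.append(f"{where}/root: not a valid identifier: {root!r}")
                continue
            if root not in store.concepts:
                problems.append(f"{where}/root: undeclared concept {root}")
                continue
            variants = []
            ok = True
            vspecs = tspec.get("variants") or []
            if not _expect(vspecs, list, f"{where}/variants", problems):
                continue
            if not vspecs:
                problems.append(f"{where}/variants: at least one variant required")
                continue
            for vi, vspec in enumerate(vspecs):
                vwhere = f"{where}/variants/{vi}"
                if not _expect(vspec if vspec is not None else {}, dict,
                               vwhere, problems):
                    ok = False
                    continue
                edges = {}
                for parent, children in (vspec or {}).items():
                    if parent not in store.concepts:
                        problems.append(f"{vwhere}/{parent}: undeclared concept")
                        ok = False
                    if not _expect(children, list, f"{vwhere}/{parent}", problems):
                        ok = False
                        continue
                    for c in children:
                        if c not in store.concepts:
                            problems.append(
                                f"{vwhere}/{parent}: undeclared child {c!r}")
                            ok = False
                    edges[parent] = children
                variants.append(TreeVariant(edges, extra_nodes=(root,)))
            if not ok:
                continue
            ts = TreeSet(root, variants)
            for node in sorted(ts.nodes):
                if node in claimed:
                    problems.append(
                        f"{where}: concept {node} already belongs to treeset "
                        f"{claimed[node]}")
                else:
                    claimed[node] = ti
            if not any(f"{where}:" in p or p.startswith(where) for p in problems):
                store.treesets.append(ts)
                store._touch()

    synonyms = doc.get("synonyms") or []
    if _expect(synonyms, list, "synonyms", problems):
        for si, s in enumerate(synonyms):
            where = f"synonyms/{si}"
            if not _expect(s, dict, where, problems):
                continue
            name, concept = s.get("name"), s.get("concept")
            if not _expect(name, str, f"{where}/name", problems):
                continue
            if concept not in store.concepts:
                problems.append(f"{where}/concept: undeclared concept {concept!r}")
                continue
            try:
                ntype = NameType(s.get("type", "scientific"))
            except ValueError:
                problems.append(f"{where}/type: invalid type {s.get('type')!r}")
                continue
            store.synonyms.append(SynonymEntry(name, concept, ntype,
                                               s.get("language")))

    hybrids = doc.get("hybrids") or {}
    if _expect(hybrids, dict, "hybrids", problems):
        for cid, parents in sorted(hybrids.items()):
            where = f"hybrids/{cid}"
            if cid not in store.concepts:
                problems.append(f"{where}: undeclared concept")
                continue
            if not _expect(parents, list, where, problems):
                continue
            bad = [p for p in parents if p not in store.concepts]
            for p in bad:
                problems.append(f"{where}: undeclared parent {p!r}")
            if not bad:
                store.hybrids[cid] = tuple(sorted(parents))

    if problems:
        raise StoreSchemaError(problems)
    store._touch()
    return store


# ---------------------------------------------------------------------------
# scope files (one leaf concept ID per line)


def read_scope(path: Union[str, os.PathLike]) -> frozenset[str]:
    ids = [l.strip() for l in Path(path).read_text(encoding="utf-8").splitlines()
           if l.strip() and not l.startswith("#")]
    return frozenset(ids)


def write_scope(scope, path: Union[str, os.PathLike]) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in sorted(scope)),
                          encoding="utf-8")
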