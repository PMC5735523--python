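"""OBO 1.4 flat-file ingestion.

Parsing of the stanza structure is delegated to :mod:`obonet`; this
module maps the parsed graph onto the EL axiom model:

* ``is_a`` lines become ``SubClassOf(Named, Named)``;
* ``relationship: r T`` lines become ``SubClassOf(Named, r some T)``;
* ``intersection_of`` blocks (genus + differentia) become
  ``EquivalentClasses(Named, genus and (r some T) and ...)``;
* ``[Typedef]`` stanzas provide role hierarchy and the
  transitive/reflexive flags.

Obsolete terms are excluded; their ``alt_id`` lines on live terms are
recorded as cross-references so stale identifiers in mapping files can
still be resolved.
"""

from __future__ import annotations

import logging
import re

import obonet

from .model import (
    EquivalentClasses,
    Existential,
    Named,
    OntologySnapshot,
    SubClassOf,
    conj,
    normalize_id,
)

logger = logging.getLogger(__name__)

_SYNONYM = re.compile(r'^"((?:[^"\\]|\\.)*)"')
_TAG_LINE = re.compile(r"^[\w-]+:")


class OboParseError(ValueError):
    pass


def _prescan(path: str) -> None:
    """Reject structurally malformed stanza lines with a line number."""
    with open(path, encoding="utf-8") as fh:
        in_stanza = False
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("!"):
                continue
            if stripped.startswith("[") and stripped.endswith("]"):
                in_stanza = True
                continue
            if in_stanza and not _TAG_LINE.match(stripped):
                raise OboParseError(
                    f"{path}:{lineno}: malformed stanza line: {stripped!r}")


def _norm(raw: str) -> str:
    return normalize_id(raw)


def parse_obo(path: str) -> OntologySnapshot:
    """Parse an OBO 1.4 flat file into an :class:`OntologySnapshot`."""
    _prescan(path)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # malformed headers/stanzas obonet rejects
        raise OboParseError(f"{path}: {exc}") from exc

    snap = OntologySnapshot()
    declared_roles: set[str] = set()

    for typedef in graph.graph.get("typedefs", []):
        try:
            rid = _norm(typedef["id"])
        except ValueError:
            rid = typedef["id"]
        declared_roles.add(rid)
        parents = []
        for p in typedef.get("is_a", []):
            try:
                parents.append(_norm(p))
            except ValueError:
                parents.append(p)
        snap.add_role(
            rid,
            transitive=str(typedef.get("is_transitive", "")).lower() == "true",
            reflexive=str(typedef.get("is_reflexive", "")).lower() == "true",
            parents=parents,
        )

    def role_id(token: str) -> str:
        try:
            rid = _norm(token)
        except ValueError:
            rid = token
        if rid not in snap.roles:
            if rid not in declared_roles:
                logger.warning("%s: relationship type %r used without a [Typedef]; "
                               "auto-registering", path, token)
            snap.add_role(rid)
        return rid

    for node, data in graph.nodes(data=True):
        curie = _norm(node)
        snap.add_class(curie, data.get("name"))
        for syn_line in data.get("synonym", []):
            m = _SYNONYM.match(syn_line)
            if m:
                snap.synonyms.setdefault(curie, set()).add(m.group(1))
        for xref in data.get("xref", []):
            token = xref.split('"')[0].strip().split(" ")[0]
            try:
                snap.xrefs.setdefault(curie, set()).add(_norm(token))
            except ValueError:
                pass
        for alt in data.get("alt_id", []):
            try:
                snap.xrefs.setdefault(curie, set()).add(_norm(alt))
            except ValueError:
                pass
        for parent in data.get("is_a", []):
            snap.axioms.append(SubClassOf(Named(curie), Named(_norm(parent))))
        for rel_line in data.get("relationship", []):
            parts = rel_line.split()
            if len(parts) < 2:
                raise OboParseError(f"{path}: malformed relationship line {rel_line!r} "
                                    f"on {curie}")
            rel, target = parts[0], parts[1]
            snap.axioms.append(
                SubClassOf(Named(curie), Existential(role_id(rel), Named(_norm(target)))))
        inter = data.get("intersection_of", [])
        if inter:
            operands = []
            for line in inter:
                parts = line.split()
                if len(parts) == 1:
                    operands.append(Named(_norm(parts[0])))
                else:
                    operands.append(Existential(role_id(parts[0]), Named(_norm(parts[1]))))
            snap.axioms.append(EquivalentClasses([Named(curie), conj(*operands)]))

    # register every class referenced by an axiom but lacking its own stanza
    snap.classes |= snap.referenced_curies()
    return snap
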