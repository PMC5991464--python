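"""Drug-label XML I/O in the TAC-2017 dialect.

A label document has three parts: ``Text`` (free-text sections from the
ADR-relevant parts of the label), optional ``Mentions`` (manually curated ADR
spans) and optional ``Reactions`` (label-level ADRs normalized to preferred
terms). Offsets are 0-based, half-open, in characters, per section.

The dialect is mimicked, not byte-locked: unknown attributes round-trip
unchanged so files from related corpora stay readable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

from lxml import etree

from .errors import OffsetError, ParseError

_KNOWN_SECTION_ATTRS = ("id", "name")
_KNOWN_MENTION_ATTRS = ("id", "section", "type", "start", "len", "str")

#: Default cue for table-header lines: no lowercase letters, at least one
#: uppercase letter, minimum length 4.
DEFAULT_HEADER_LINE_RE = r"^(?=.*[A-Z])[^a-z]{4,}$"


@dataclass(frozen=True)
class GoldMention:
    """One curated ADR span in a section's text."""

    section_id: str
    start: int
    length: int
    mention_type: str
    surface: str
    extra: tuple[tuple[str, str], ...] = ()

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class HeaderSpan:
    """A section-title or table-header span, excluded from tagging."""

    section_id: str
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class Section:
    section_id: str
    title: str
    text: str
    extra: tuple[tuple[str, str], ...] = ()


@dataclass
class LabelDocument:
    """One drug label: sections plus optional gold annotations.

    ``gold_mentions``/``gold_reactions`` are ``None`` (absent, as in the
    unannotated part of a corpus) when the corresponding XML sections are
    missing, and empty containers when present but empty.
    """

    drug_name: str
    label_id: str
    sections: list[Section] = field(default_factory=list)
    gold_mentions: Optional[list[GoldMention]] = None
    gold_reactions: Optional[frozenset[str]] = None

    def section(self, section_id: str) -> Section:
        for s in self.sections:
            if s.section_id == section_id:
                return s
        raise KeyError(section_id)

    def validate(self) -> None:
        ids = [s.section_id for s in self.sections]
        if len(ids) != len(set(ids)):
            raise ParseError(f"{self.label_id}: duplicate section ids")
        for m in self.gold_mentions or []:
            text = self.section(m.section_id).text
            if m.start < 0 or m.end > len(text):
                raise OffsetError(
                    f"{self.label_id}: mention {m.surface!r} at "
                    f"[{m.start}, {m.end}) outside section {m.section_id}"
                )
            if text[m.start : m.end] != m.surface:
                raise OffsetError(
                    f"{self.label_id}: mention surface {m.surface!r} != section "
                    f"slice {text[m.start:m.end]!r} at [{m.start}, {m.end})"
                )


def read_label_xml(path) -> LabelDocument:
    """Parse one label XML file; offset-checks every gold mention."""
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "Label":
        raise ParseError(f"{path}: root element is {root.tag!r}, expected 'Label'")
    drug = root.get("drug", "")
    label_id = root.get("id", drug)

    sections: list[Section] = []
    text_el = root.find("Text")
    if text_el is not None:
        for sec in text_el.findall("Section"):
            extra = tuple(
                sorted((k, v) for k, v in sec.attrib.items() if k not in _KNOWN_SECTION_ATTRS)
            )
            sections.append(
                Section(
                    section_id=sec.get("id", f"S{len(sections) + 1}"),
                    title=sec.get("name", ""),
                    text=sec.text or "",
                    extra=extra,
                )
            )

    gold_mentions = None
    mentions_el = root.find("Mentions")
    if mentions_el is not None:
        gold_mentions = []
        for m in mentions_el.findall("Mention"):
            try:
                start = int(m.get("start"))
                length = int(m.get("len"))
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: Mention with non-integer offsets") from exc
            extra = tuple(
                sorted((k, v) for k, v in m.attrib.items() if k not in _KNOWN_MENTION_ATTRS)
            )
            gold_mentions.append(
                GoldMention(
                    section_id=m.get("section", ""),
                    start=start,
                    length=length,
                    mention_type=m.get("type", "AdverseReaction"),
                    surface=m.get("str", ""),
                    extra=extra,
                )
            )

    gold_reactions = None
    reactions_el = root.find("Reactions")
    if reactions_el is not None:
        ids = set()
        for r in reactions_el.findall("Reaction"):
            for n in r.findall("Normalization"):
                term_id = n.get("meddra_pt_id") or n.get("term_id")
                if term_id:
                    ids.add(term_id)
        gold_reactions = frozenset(ids)

    doc = LabelDocument(
        drug_name=drug,
        label_id=label_id,
        sections=sections,
        gold_mentions=gold_mentions,
        gold_reactions=gold_reactions,
    )
    doc.validate()
    return doc


def write_label_xml(doc: LabelDocument, path) -> None:
    """Serialize a document; ``read_label_xml`` round-trips it field-for-field."""
    doc.validate()
    root = etree.Element("Label", drug=doc.drug_name, id=doc.label_id)
    text_el = etree.SubElement(root, "Text")
    for sec in doc.sections:
        el = etree.SubElement(text_el, "Section", id=sec.section_id, name=sec.title)
        for k, v in sec.extra:
            el.set(k, v)
        el.text = sec.text
    if doc.gold_mentions is not None:
        mentions_el = etree.SubElement(root, "Mentions")
        for i, m in enumerate(doc.gold_mentions, start=1):
            el = etree.SubElement(
                mentions_el,
                "Mention",
                id=f"M{i}",
                section=m.section_id,
                type=m.mention_type,
                start=str(m.start),
                len=str(m.length),
            )
            el.set("str", m.surface)
            for k, v in m.extra:
                el.set(k, v)
    if doc.gold_reactions is not None:
        reactions_el = etree.SubElement(root, "Reactions")
        for i, term_id in enumerate(sorted(doc.gold_reactions), start=1):
            r = etree.SubElement(reactions_el, "Reaction", id=f"R{i}")
            etree.SubElement(r, "Normalization", id=f"RN{i}", meddra_pt_id=term_id)
    etree.ElementTree(root).write(
        str(path), encoding="utf-8", xml_declaration=True, pretty_print=False
    )


def detect_headers(
    doc: LabelDocument, header_line_re: str = DEFAULT_HEADER_LINE_RE
) -> list[HeaderSpan]:
    """Spans over section titles and table-header lines within section text.

    A line is a header if it equals the section title (case-insensitive) or
    matches ``header_line_re`` after stripping surrounding whitespace.
    """
    pattern = re.compile(header_line_re)
    spans: list[HeaderSpan] = []
    for sec in doc.sections:
        title = sec.title.strip().casefold()
        pos = 0
        for line in sec.text.split("\n"):
            stripped = line.strip()
            if stripped and (
                (title and stripped.casefold() == title) or pattern.match(stripped)
            ):
                offset = pos + line.index(stripped)
                spans.append(HeaderSpan(sec.section_id, offset, len(stripped)))
            pos += len(line) + 1
    return spans


def copy_without_gold(doc: LabelDocument) -> LabelDocument:
    """The same label with annotations removed (an 'unannotated set' view)."""
    return replace(doc, gold_mentions=None, gold_reactions=None)
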