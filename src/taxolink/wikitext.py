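"""MediaWiki dump streaming and Taxobox parsing.

Pages come from the MediaWiki XML export format (the ``Special:Export`` /
``dumps.wikimedia.org`` schema: ``<mediawiki><page><title><ns><id>
<revision><text>``).  :func:`iterate_pages` streams it with lxml's
``iterparse`` in constant memory.

Taxon pages are recognised by the presence of a ``{{Taxobox}}`` template.
The template is parsed by a small bracket-depth scanner: top-level ``|``
separate parameters, while pipes inside nested ``{{...}}`` templates or
``[[...|...]]`` links do not split fields.  Values are reduced to plain
text (links to their labels, bold/italic quotes, ``<ref>`` elements, HTML
comments and nested templates removed).

The scientific name of the page's taxon is taken from the ``binomial``
field when present, otherwise from the lowest populated classification
field, expanding an abbreviated epithet ("H. chaophraya") against the
genus field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterator

from lxml import etree

from .errors import ParseError
from .taxdump import normalize_name

#: Classification keys of the Taxobox in descending rank order; the last
#: populated one is the "lowest" rank on the page.
RANK_KEYS = ("regnum", "phylum", "classis", "subclassis",
             "ordo", "familia", "genus", "species")

#: Templates that mark a page as a disambiguation page (lower-cased).
DEFAULT_DISAMBIG_TEMPLATES = frozenset({
    "disambiguation", "disambig", "dab", "disamb", "hndis",
    "geodis", "species latin name disambiguation",
})

#: Infobox template names accepted as a taxon box. Later variants such as
#: "Automatic taxobox" or "Speciesbox" can be enabled via configuration.
DEFAULT_TAXOBOX_ALIASES = ("Taxobox",)

_REDIRECT_RE = re.compile(
    r"\A\s*#\s*redirect\s*:?\s*\[\[([^\]|#]+)", re.IGNORECASE)


@dataclass(frozen=True)
class WikiPage:
    """One page of a dump: stable numeric id, title, namespace, wikitext
    and — for redirect pages — the redirect target title."""

    title: str
    page_id: int
    namespace: int
    wikitext: str
    redirect_target: str | None = None

    @property
    def is_redirect(self) -> bool:
        return self.redirect_target is not None


@dataclass
class Taxobox:
    """Structured view of a Taxobox template."""

    display_name: str | None = None
    binomial: str | None = None
    binomial_authority: str | None = None
    image: str | None = None
    status: str | None = None
    rank_fields: dict[str, str] = field(default_factory=dict)  # insertion-ordered

    @property
    def regnum(self) -> str | None:
        return self.rank_fields.get("regnum")


def canonical_title(title: str) -> str:
    """MediaWiki main-namespace canonical form: underscores become spaces,
    space runs collapse, the first character is uppercased."""
    t = normalize_name(title.replace("_", " "))
    if not t:
        raise ValueError("empty page title")
    return t[0].upper() + t[1:]


def url_form(title: str) -> str:
    """Inverse of :func:`canonical_title` for links/URIs: spaces → underscores."""
    return canonical_title(title).replace(" ", "_")


def detect_redirect(wikitext: str) -> str | None:
    """Target title of a leading ``#REDIRECT [[...]]`` directive, in
    canonical form; None for ordinary articles."""
    m = _REDIRECT_RE.match(wikitext or "")
    if not m:
        return None
    target = m.group(1).strip()
    return canonical_title(target) if target else None


def _strip_comments(text: str) -> str:
    return re.sub(r"<!--.*?-->", "", text, flags=re.DOTALL)


def _strip_refs(text: str) -> str:
    text = re.sub(r"<ref[^>/]*/\s*>", "", text)
    return re.sub(r"<ref[^>]*>.*?</ref>", "", text, flags=re.DOTALL | re.IGNORECASE)


def _strip_templates(text: str) -> str:
    """Remove ``{{...}}`` regions, tracking nesting depth."""
    out = []
    depth = 0
    i = 0
    n = len(text)
    while i < n:
        if text.startswith("{{", i):
            depth += 1
            i += 2
        elif text.startswith("}}", i) and depth:
            depth -= 1
            i += 2
        else:
            if depth == 0:
                out.append(text[i])
            i += 1
    return "".join(out)


_FILE_PREFIXES = ("file:", "image:", "category:")


def _reduce_links(text: str) -> str:
    """``[[target|label]]`` → label, ``[[target]]`` → target; file, image
    and category links (which may nest brackets in their captions) are
    removed outright."""
    out = []
    i = 0
    n = len(text)
    while i < n:
        if text.startswith("[[", i):
            depth = 1
            j = i + 2
            while j < n and depth:
                if text.startswith("[[", j):
                    depth += 1
                    j += 2
                elif text.startswith("]]", j):
                    depth -= 1
                    j += 2
                else:
                    j += 1
            inner = text[i + 2:j - 2] if depth == 0 else text[i + 2:]
            if inner.lstrip().lower().startswith(_FILE_PREFIXES):
                pass  # drop media/category links entirely
            else:
                head, _, label = inner.partition("|")
                out.append((label or head).strip() or head.strip())
            i = j
        else:
            out.append(text[i])
            i += 1
    return "".join(out)


def strip_markup(text: str) -> str:
    """Reduce a wikitext fragment to plain text."""
    text = _strip_comments(text)
    text = _strip_refs(text)
    text = _strip_templates(text)
    text = _reduce_links(text)
    text = text.replace("'''", "").replace("''", "")
    text = re.sub(r"<[^>]+>", "", text)  # residual inline HTML tags
    return normalize_name(text)


def split_template_params(body: str) -> list[str]:
    """Split a template body on top-level pipes.

    Pipes inside nested ``{{...}}`` templates or ``[[...]]`` links are part
    of the enclosing parameter and must not split it.
    """
    parts: list[str] = []
    buf: list[str] = []
    tdepth = 0
    ldepth = 0
    i = 0
    n = len(body)
    while i < n:
        if body.startswith("{{", i):
            tdepth += 1
            buf.append("{{")
            i += 2
        elif body.startswith("}}", i) and tdepth:
            tdepth -= 1
            buf.append("}}")
            i += 2
        elif body.startswith("[[", i):
            ldepth += 1
            buf.append("[[")
            i += 2
        elif body.startswith("]]", i) and ldepth:
            ldepth -= 1
            buf.append("]]")
            i += 2
        elif body[i] == "|" and tdepth == 0 and ldepth == 0:
            parts.append("".join(buf))
            buf = []
            i += 1
        else:
            buf.append(body[i])
            i += 1
    parts.append("".join(buf))
    return parts


def find_template(wikitext: str, name: str) -> str | None:
    """Return the body (without braces) of the first top-level template
    whose name matches ``name`` (first letter case-insensitive), or None.

    Unbalanced braces make the template unusable and yield None.
    """
    pattern = re.compile(
        r"\{\{\s*[" + re.escape(name[0].upper()) + re.escape(name[0].lower())
        + r"]" + re.escape(name[1:]) + r"\s*(?=[|}\n])")
    for m in pattern.finditer(wikitext):
        start = m.start()
        depth = 0
        i = start
        n = len(wikitext)
        while i < n:
            if wikitext.startswith("{{", i):
                depth += 1
                i += 2
            elif wikitext.startswith("}}", i):
                depth -= 1
                i += 2
                if depth == 0:
                    return wikitext[start + 2:i - 2]
            else:
                i += 1
        return None  # unbalanced braces: skip
    return None


def template_fields(body: str) -> dict[str, str]:
    """Key → raw value of the named parameters of a template body,
    preserving template order (first occurrence wins)."""
    fields: dict[str, str] = {}
    for part in split_template_params(body)[1:]:
        key, eq, value = part.partition("=")
        if not eq:
            continue
        key = key.strip()
        if key and key not in fields:
            fields[key] = value.strip()
    return fields


def extract_taxobox(wikitext: str,
                    aliases: tuple[str, ...] = DEFAULT_TAXOBOX_ALIASES
                    ) -> Taxobox | None:
    """Parse the first taxon infobox on the page, if any."""
    body = None
    for alias in aliases:
        body = find_template(_strip_comments(wikitext or ""), alias)
        if body is not None:
            break
    if body is None:
        return None
    raw = template_fields(body)
    box = Taxobox()
    for key, value in raw.items():
        clean = strip_markup(value)
        if key in RANK_KEYS:
            if clean:
                box.rank_fields[key] = clean
        elif key == "name":
            box.display_name = clean or None
        elif key == "binomial":
            box.binomial = clean or None
        elif key == "binomial_authority":
            box.binomial_authority = clean or None
        elif key == "image":
            box.image = clean or None
        elif key == "status":
            box.status = clean or None
    return box


_ABBREV_RE = re.compile(r"\A([A-Z])\.\s*(\S.*)\Z")


def page_scientific_name(taxobox: Taxobox | None) -> str | None:
    """Scientific name of the taxon a page is about.

    Priority: the ``binomial`` field; else the lowest populated
    classification field, expanding an abbreviated species epithet
    ("H. chaophraya") against the genus when the initials agree.
    """
    if taxobox is None:
        return None
    if taxobox.binomial:
        return taxobox.binomial
    for key in reversed(RANK_KEYS):
        value = taxobox.rank_fields.get(key)
        if not value:
            continue
        if key == "species":
            m = _ABBREV_RE.match(value)
            genus = taxobox.rank_fields.get("genus")
            if m and genus and genus[0] == m.group(1):
                return f"{genus} {m.group(2)}"
        return value
    return None


_HEADING_RE = re.compile(r"^=+[^=\n]+=+\s*$", re.MULTILINE)
_SENTENCE_END = re.compile(r"(?<=[.!?])\s+")


def lead_snippet(wikitext: str, max_chars: int = 300) -> str:
    """Plain-text lead of an article, truncated at a sentence boundary.

    Templates, media links, references and markup are removed; the text
    before the first section heading is kept; whole sentences are
    accumulated while they fit in ``max_chars``, with an ellipsis appended
    when truncated.  If not even the first sentence fits, the text is cut
    at the last word boundary within the budget.
    """
    if max_chars <= 0:
        raise ValueError("max_chars must be positive")
    m = _HEADING_RE.search(wikitext or "")
    lead = wikitext[: m.start()] if m else (wikitext or "")
    text = strip_markup(lead)
    if not text:
        return ""
    if len(text) <= max_chars:
        return text
    sentences = _SENTENCE_END.split(text)
    out = ""
    for s in sentences:
        candidate = (out + " " + s).strip()
        if len(candidate) > max_chars:
            break
        out = candidate
    if not out:  # first sentence alone exceeds the budget
        out = text[:max_chars].rsplit(" ", 1)[0].rstrip()
    return out + "..."


def is_disambiguation(wikitext: str,
                      templates: frozenset[str] = DEFAULT_DISAMBIG_TEMPLATES
                      ) -> bool:
    """True if the page transcludes a disambiguation template."""
    for m in re.finditer(r"\{\{\s*([^|{}]+?)\s*(?:[|}\n])", wikitext or ""):
        if m.group(1).strip().lower() in templates:
            return True
    return False


def _localname(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _child_text(elem, name: str) -> str | None:
    for ch in elem:
        if _localname(ch.tag) == name:
            return ch.text or ""
    return None


def iterate_pages(source: str | IO[bytes]) -> Iterator[WikiPage]:
    """Stream :class:`WikiPage` objects from a MediaWiki XML export.

    ``source`` is a path or a binary file object.  Memory use is constant
    in the dump size: each ``<page>`` element is discarded once yielded.
    The latest ``<revision><text>`` is used.
    """
    try:
        for _event, elem in etree.iterparse(source, events=("end",)):
            if _localname(elem.tag) != "page":
                continue
            title = _child_text(elem, "title") or ""
            ns = int(_child_text(elem, "ns") or 0)
            page_id = int(_child_text(elem, "id") or 0)
            text = ""
            for ch in elem:
                if _localname(ch.tag) == "revision":
                    text = _child_text(ch, "text") or ""
            yield WikiPage(
                title=canonical_title(title) if title else "",
                page_id=page_id,
                namespace=ns,
                wikitext=text,
                redirect_target=detect_redirect(text),
            )
            elem.clear()
            parent = elem.getparent()
            if parent is not None:
                while elem.getprevious() is not None:
                    del parent[0]
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML export: {exc.msg}",
                         offset=getattr(exc, "position", (None, None))[1]) from exc
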