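"""HED annotation strings: parsing, serialization, equality, and search.

An annotation string is a comma-separated sequence of tags and arbitrarily
nested parenthesized groups, e.g. ``(Index-finger, (Press, Keyboard-key))``.
Tags may be written short form (``Circle``), long form
(``Item/Object/Geometric-object/2D-shape/Ellipse/Circle``), or with a value
suffix on a takes-value node (``Item-count/2``, ``Pathname/f032.bmp``).
The literal value ``#`` is the placeholder used by value-column templates
and parameterized definitions.

Equality of strings and groups is order-insensitive at each nesting level
(multiset semantics): concatenation order during assembly is presentational.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import HedStringParseError, UnknownTagError
from .schema import HedSchema, SchemaNode, subsumes

PLACEHOLDER = "#"


@dataclass(frozen=True)
class HedTag:
    """A single resolved tag: a schema node plus an optional value suffix."""

    node: SchemaNode
    value: str | None = None
    source_text: str = ""

    def short(self) -> str:
        if self.value is not None:
            return f"{self.node.name}/{self.value}"
        return self.node.name

    def long(self) -> str:
        if self.value is not None:
            return f"{self.node.long_path}/{self.value}"
        return self.node.long_path

    @property
    def name(self) -> str:
        return self.node.name

    def __str__(self) -> str:
        return self.short()


class HedGroup:
    """A parenthesized group: an ordered list of tags and subgroups."""

    __slots__ = ("items",)

    def __init__(self, items: list["HedTag | HedGroup"]):
        self.items = items

    def tags(self):
        """Direct child tags (non-recursive)."""
        return [it for it in self.items if isinstance(it, HedTag)]

    def groups(self):
        """Direct child groups (non-recursive)."""
        return [it for it in self.items if isinstance(it, HedGroup)]

    def iter_tags(self):
        """All tags, recursing into subgroups."""
        for item in self.items:
            if isinstance(item, HedTag):
                yield item
            else:
                yield from item.iter_tags()

    def __eq__(self, other) -> bool:
        return isinstance(other, HedGroup) and _norm_group(self) == _norm_group(other)

    def __hash__(self) -> int:
        return hash(_norm_group(self))

    def __str__(self) -> str:
        return serialize_item(self, "short")


class HedString:
    """A parsed annotation: the ordered top-level tags and groups."""

    __slots__ = ("items",)

    def __init__(self, items: list[HedTag | HedGroup] | None = None):
        self.items = items or []

    def is_empty(self) -> bool:
        return not self.items

    def tags(self):
        return [it for it in self.items if isinstance(it, HedTag)]

    def groups(self):
        return [it for it in self.items if isinstance(it, HedGroup)]

    def iter_tags(self):
        for item in self.items:
            if isinstance(item, HedTag):
                yield item
            else:
                yield from item.iter_tags()

    def __eq__(self, other) -> bool:
        return isinstance(other, HedString) and _norm_items(self.items) == _norm_items(
            other.items
        )

    def __hash__(self) -> int:
        return hash(_norm_items(self.items))

    def __str__(self) -> str:
        return serialize(self, "short")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"HedString({serialize(self, 'short')!r})"


def _norm_tag(tag: HedTag):
    return tag.short().casefold()


def _norm_group(group: HedGroup):
    return ("()", _norm_items(group.items))


def _norm_items(items):
    keys = [
        _norm_tag(it) if isinstance(it, HedTag) else _norm_group(it) for it in items
    ]
    return tuple(sorted(keys, key=repr))


# ---------------------------------------------------------------------------
# Parsing


def resolve_tag(text: str, schema: HedSchema) -> HedTag:
    """Resolve one tag token against the schema.

    Accepts a short name, a full or partial long-form path (validated
    component by component), and a trailing ``/value`` on takes-value nodes.
    """
    token = text.strip()
    if not token:
        raise HedStringParseError("empty tag")
    if token == PLACEHOLDER:
        raise HedStringParseError(
            "'#' placeholder must follow a takes-value tag name (e.g. 'Pathname/#')"
        )
    components = token.split("/")
    # Longest path prefix that matches a schema node, scanning from the
    # deepest component back toward the start.
    for k in range(len(components), 0, -1):
        name = components[k - 1].strip()
        if not name or name not in schema:
            continue
        node = schema.get(name)
        path = node.long_path.split("/")
        prefix = [c.strip() for c in components[:k]]
        if len(prefix) > len(path):
            continue
        if [p.casefold() for p in path[-len(prefix):]] != [
            p.casefold() for p in prefix
        ]:
            continue
        rest = "/".join(c.strip() for c in components[k:])
        if not rest:
            return HedTag(node=node, source_text=token)
        if not node.takes_value:
            raise HedStringParseError(
                f"tag {node.name!r} does not take a value (in {token!r})"
            )
        return HedTag(node=node, value=rest, source_text=token)
    raise UnknownTagError(f"unknown tag {token!r}")


def _split_top_level(text: str) -> list[str]:
    """Split on commas not enclosed in parentheses; validates balance."""
    pieces, depth, start = [], 0, 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise HedStringParseError(
                    f"unbalanced ')' at position {i} in {text!r}"
                )
        elif ch == "," and depth == 0:
            pieces.append(text[start:i])
            start = i + 1
    if depth != 0:
        raise HedStringParseError(f"unbalanced '(' in {text!r}")
    pieces.append(text[start:])
    return pieces


def _parse_items(text: str, schema: HedSchema) -> list[HedTag | HedGroup]:
    items: list[HedTag | HedGroup] = []
    for piece in _split_top_level(text):
        piece = piece.strip()
        if not piece:
            raise HedStringParseError(f"empty tag between commas in {text!r}")
        if piece.startswith("(") and piece.endswith(")") and _is_whole_group(piece):
            inner = piece[1:-1].strip()
            if not inner:
                raise HedStringParseError("empty group '()'")
            items.append(HedGroup(_parse_items(inner, schema)))
        else:
            items.append(resolve_tag(piece, schema))
    return items


def _is_whole_group(piece: str) -> bool:
    """True if the outermost parens of *piece* enclose the entire piece."""
    depth = 0
    for i, ch in enumerate(piece):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth == 0:
                return i == len(piece) - 1
    return False


def parse_hed_string(text: str, schema: HedSchema) -> HedString:
    """Parse annotation text into a :class:`HedString`.

    An empty (or all-whitespace) string parses to an empty HedString.
    """
    if not text or not text.strip():
        return HedString([])
    return HedString(_parse_items(text, schema))


# ---------------------------------------------------------------------------
# Serialization


def serialize_item(item: HedTag | HedGroup, form: str) -> str:
    if isinstance(item, HedTag):
        return item.long() if form == "long" else item.short()
    inner = ", ".join(serialize_item(it, form) for it in item.items)
    return f"({inner})"


def serialize(hs: HedString, form: str = "short") -> str:
    """Serialize to text; ``form`` is ``"short"`` or ``"long"``."""
    if form not in ("short", "long"):
        raise ValueError(f"form must be 'short' or 'long', got {form!r}")
    return ", ".join(serialize_item(item, form) for item in hs.items)


# ---------------------------------------------------------------------------
# Search


def search(hs: HedString, query: str, schema: HedSchema) -> list[HedTag]:
    """Find all tags in *hs* whose node is subsumed by the *query* node.

    The query resolves case-insensitively; an unknown query raises
    :class:`UnknownTagError`.  Matching recurses into nested groups.
    """
    query_node = schema.get(query)  # raises UnknownTagError
    return [
        tag
        for tag in hs.iter_tags()
        if subsumes(schema, query_node.name, tag.node.name)
    ]


# ---------------------------------------------------------------------------
# Structural helpers shared by downstream modules


def copy_item(item: HedTag | HedGroup) -> HedTag | HedGroup:
    """Deep-copy a tag or group (tags are immutable and shared)."""
    if isinstance(item, HedTag):
        return item
    return HedGroup([copy_item(it) for it in item.items])


def substitute_placeholder(hs: HedString, value: str) -> HedString:
    """Return a copy of *hs* with every ``#`` inside tag values replaced.

    Used for value-column templates and parameterized definition bodies.
    """

    def _sub(item):
        if isinstance(item, HedTag):
            if item.value is not None and PLACEHOLDER in item.value:
                return HedTag(
                    node=item.node,
                    value=item.value.replace(PLACEHOLDER, value),
                    source_text=item.source_text,
                )
            return item
        return HedGroup([_sub(it) for it in item.items])

    return HedString([_sub(it) for it in hs.items])


def count_placeholders(items) -> int:
    """Number of ``#`` occurrences in tag values across *items* (recursive)."""
    n = 0
    for item in items:
        if isinstance(item, HedTag):
            if item.value is not None:
                n += item.value.count(PLACEHOLDER)
        else:
            n += count_placeholders(item.items)
    return n
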