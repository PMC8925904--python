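"""Hierarchical vocabulary schema: parsing, unique-name index, subsumption.

The schema is a rooted forest of uniquely named nodes.  Because every name
is unique across the forest, annotators may write the short form (the bare
node name) and tools expand it to the full slash-joined root-to-node path
(the long form).  Lookup is case-insensitive; the capitalization declared
in the schema document is canonical for output.

Schema document format (plain text, UTF-8)
------------------------------------------
One node per line; nesting by indentation of two spaces per level::

    Item : An independently existing thing.
      Object
        Geometric-object
          2D-shape
            Ellipse
              Circle

* A node name contains no whitespace (words are hyphenated).
* Optional description follows a `` : `` separator.
* A child line consisting of a single ``#`` marks the parent as a
  *takes-value* node: it admits a ``/value`` suffix (e.g. ``Item-count/2``)
  and may have no other children.
* Blank lines are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DuplicateNodeError, SchemaParseError, UnknownTagError

_INDENT = 2


@dataclass
class SchemaNode:
    """A single vocabulary term."""

    name: str
    parent: "SchemaNode | None" = None
    children: list["SchemaNode"] = field(default_factory=list)
    takes_value: bool = False
    description: str = ""

    @property
    def long_path(self) -> str:
        """Slash-joined path from the root down to this node."""
        parts = []
        node: SchemaNode | None = self
        while node is not None:
            parts.append(node.name)
            node = node.parent
        return "/".join(reversed(parts))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SchemaNode({self.long_path!r})"


class HedSchema:
    """A rooted forest of :class:`SchemaNode` with a unique-name index."""

    def __init__(self, roots: list[SchemaNode]):
        self.roots = roots
        self._index: dict[str, SchemaNode] = {}
        for root in roots:
            self._register(root)

    def _register(self, node: SchemaNode) -> None:
        key = node.name.casefold()
        if key in self._index:
            other = self._index[key]
            raise DuplicateNodeError(
                f"duplicate node name {node.name!r}: declared at "
                f"{other.long_path!r} and {node.long_path!r}"
            )
        self._index[key] = node
        for child in node.children:
            self._register(child)

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, name: str) -> bool:
        return name.casefold() in self._index

    def get(self, name: str) -> SchemaNode:
        """Resolve a short name case-insensitively.

        Raises :class:`UnknownTagError` if the name is not in the schema.
        """
        try:
            return self._index[name.casefold()]
        except KeyError:
            raise UnknownTagError(f"unknown tag {name!r}") from None

    def nodes(self):
        """Iterate over all nodes (document order)."""
        stack = list(reversed(self.roots))
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


def long_path(schema: HedSchema, short_name: str) -> str:
    """Expand a short name to its full root-to-node path."""
    return schema.get(short_name).long_path


def subsumes(schema: HedSchema, ancestor_name: str, descendant_name: str) -> bool:
    """True iff *ancestor* lies on the root path of *descendant* (inclusive)."""
    ancestor = schema.get(ancestor_name)
    node: SchemaNode | None = schema.get(descendant_name)
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


def parse_schema(text: str) -> HedSchema:
    """Parse a schema document (see module docstring for the format)."""
    roots: list[SchemaNode] = []
    # stack[i] = most recent node at depth i
    stack: list[SchemaNode] = []
    saw_entry = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        stripped = raw.lstrip(" ")
        indent = len(raw) - len(stripped)
        if stripped.startswith("\t") or "\t" in raw[:indent]:
            raise SchemaParseError("tabs are not allowed in indentation", lineno)
        if indent % _INDENT:
            raise SchemaParseError(
                f"indentation must be a multiple of {_INDENT} spaces", lineno
            )
        depth = indent // _INDENT
        if depth > len(stack):
            raise SchemaParseError("indentation jumps more than one level", lineno)

        if stripped.rstrip() == "#":
            if depth == 0:
                raise SchemaParseError("'#' marker requires a parent node", lineno)
            parent = stack[depth - 1]
            parent.takes_value = True
            continue

        name, _, description = stripped.partition(" : ")
        name = name.rstrip()
        if not name:
            raise SchemaParseError("empty node name", lineno)
        if any(ch.isspace() for ch in name):
            raise SchemaParseError(
                f"node name {name!r} contains whitespace (hyphenate words)", lineno
            )
        node = SchemaNode(name=name, description=description.strip())
        saw_entry = True
        if depth == 0:
            roots.append(node)
        else:
            parent = stack[depth - 1]
            node.parent = parent
            parent.children.append(node)
        del stack[depth:]
        stack.append(node)

    if not saw_entry:
        raise SchemaParseError("schema document declares no nodes")

    schema = HedSchema(roots)  # raises DuplicateNodeError on clashes
    for node in schema.nodes():
        if node.takes_value and node.children:
            raise SchemaParseError(
                f"takes-value node {node.name!r} may not have children"
            )
    return schema


def load_schema(source) -> HedSchema:
    """Load a schema from a file path or an open text stream."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    return parse_schema(text)
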