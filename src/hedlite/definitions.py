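"""Named annotation concepts: Definition collection, validation, expansion.

A definition is written as a group whose first tag is ``Definition/Name``
(or ``Definition/Name/#`` for a parameterized definition); the remaining
items of the group form the body.  ``Def/Name`` references a definition
compactly, and :func:`expand_defs` replaces each reference with a
``(Def-expand/Name, <body>)`` group.  Definitions may not be nested: a
body may not contain Definition, Def, or Def-expand tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DefinitionError
from .schema import HedSchema
from .strings import (
    PLACEHOLDER,
    HedGroup,
    HedString,
    HedTag,
    copy_item,
    count_placeholders,
    substitute_placeholder,
)
from .errors import Issue

_FORBIDDEN_IN_BODY = {"definition", "def", "def-expand"}


@dataclass
class Definition:
    """A named tag-group body, optionally with one ``#`` parameter slot."""

    name: str
    body: list  # list[HedTag | HedGroup]
    takes_placeholder: bool = False
    provenance: str = ""

    def body_group(self) -> HedGroup:
        return HedGroup([copy_item(it) for it in self.body])


class DefinitionRegistry:
    """Case-insensitive mapping of definition name -> :class:`Definition`."""

    def __init__(self):
        self._entries: dict[str, Definition] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return name.casefold() in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def get(self, name: str) -> Definition:
        try:
            return self._entries[name.casefold()]
        except KeyError:
            raise DefinitionError(f"unknown definition {name!r}") from None

    def names(self) -> list[str]:
        return [d.name for d in self._entries.values()]

    def add(self, definition: Definition) -> None:
        """Register a definition; identical re-registration is idempotent."""
        key = definition.name.casefold()
        if key in self._entries:
            existing = self._entries[key]
            if _bodies_equal(existing, definition):
                return
            raise DefinitionError(
                f"conflicting definitions for {definition.name!r}: "
                f"{HedGroup(existing.body)} vs {HedGroup(definition.body)}"
            )
        self._entries[key] = definition


def _bodies_equal(a: Definition, b: Definition) -> bool:
    return (
        a.takes_placeholder == b.takes_placeholder
        and HedGroup(a.body) == HedGroup(b.body)
    )


def split_def_value(raw: str) -> tuple[str, str | None]:
    """Split a Def/Definition tag value into (name, parameter-or-None)."""
    name, sep, param = raw.partition("/")
    return name, (param if sep else None)


def _definition_tag(group: HedGroup) -> HedTag | None:
    for tag in group.tags():
        if tag.node.name.casefold() == "definition":
            return tag
    return None


def definition_from_group(group: HedGroup, provenance: str = "") -> Definition:
    """Build a :class:`Definition` from a ``(Definition/Name, ...)`` group."""
    def_tag = _definition_tag(group)
    if def_tag is None or def_tag.value is None:
        raise DefinitionError(f"group {group} is not a named definition")
    name, param = split_def_value(def_tag.value)
    takes_placeholder = param == PLACEHOLDER
    if param is not None and not takes_placeholder:
        raise DefinitionError(
            f"definition name {def_tag.value!r} may only carry a '#' parameter"
        )
    body = [it for it in group.items if it is not def_tag]
    return Definition(
        name=name,
        body=body,
        takes_placeholder=takes_placeholder,
        provenance=provenance,
    )


def is_definition_group(item) -> bool:
    return isinstance(item, HedGroup) and _definition_tag(item) is not None


def extract_definitions(
    strings: list[HedString], provenance: str = ""
) -> DefinitionRegistry:
    """Collect every top-level Definition group into a registry.

    A Definition tag at the top level of a string (outside any group) or
    buried below the top level of groups is a structural error.  Identical
    duplicates are idempotent; same-name/different-body is a hard conflict.
    """
    registry = DefinitionRegistry()
    collect_definitions(strings, registry, provenance=provenance)
    return registry


def collect_definitions(
    strings: list[HedString], registry: DefinitionRegistry, provenance: str = ""
) -> None:
    """Like :func:`extract_definitions` but adds into an existing registry."""
    for hs in strings:
        for item in hs.items:
            if isinstance(item, HedTag):
                if item.node.name.casefold() == "definition":
                    raise DefinitionError(
                        f"Definition tag {item} must be enclosed in a group"
                    )
                continue
            if is_definition_group(item):
                registry.add(definition_from_group(item, provenance=provenance))
            else:
                _check_no_buried_definitions(item)


def _check_no_buried_definitions(group: HedGroup) -> None:
    for tag in group.iter_tags():
        if tag.node.name.casefold() == "definition":
            raise DefinitionError(
                f"Definition tag {tag} may only appear in a top-level group"
            )


def strip_definitions(hs: HedString) -> HedString:
    """Return *hs* without its top-level Definition groups."""
    return HedString([it for it in hs.items if not is_definition_group(it)])


def validate_definitions(
    registry: DefinitionRegistry, schema: HedSchema | None = None
) -> list[Issue]:
    """Lint a registry: nesting, placeholder arity.  Issues are data."""
    issues: list[Issue] = []
    for definition in registry:
        for tag in HedGroup(definition.body).iter_tags():
            if tag.node.name.casefold() in _FORBIDDEN_IN_BODY:
                issues.append(
                    Issue(
                        code="nested-definition",
                        message=(
                            f"definition {definition.name!r} body contains "
                            f"{tag}; definitions cannot be nested"
                        ),
                        file=definition.provenance or None,
                    )
                )
        n_placeholders = count_placeholders(definition.body)
        if definition.takes_placeholder and n_placeholders != 1:
            issues.append(
                Issue(
                    code="placeholder-arity",
                    message=(
                        f"parameterized definition {definition.name!r} must "
                        f"contain exactly one '#', found {n_placeholders}"
                    ),
                    file=definition.provenance or None,
                )
            )
        elif not definition.takes_placeholder and n_placeholders:
            issues.append(
                Issue(
                    code="placeholder-arity",
                    message=(
                        f"definition {definition.name!r} contains '#' but "
                        "does not declare a parameter"
                    ),
                    file=definition.provenance or None,
                )
            )
    return issues


def _expand_item(item, registry: DefinitionRegistry, schema: HedSchema):
    if isinstance(item, HedTag):
        if item.node.name.casefold() == "def":
            if item.value is None:
                raise DefinitionError(f"Def tag {item} carries no definition name")
            name, param = split_def_value(item.value)
            definition = registry.get(name)
            if definition.takes_placeholder:
                if param is None:
                    raise DefinitionError(
                        f"definition {definition.name!r} requires a value "
                        f"(write Def/{definition.name}/<value>)"
                    )
                body = substitute_placeholder(
                    HedString([copy_item(it) for it in definition.body]), param
                ).items
                expand_value = f"{definition.name}/{param}"
            else:
                if param is not None:
                    raise DefinitionError(
                        f"definition {definition.name!r} takes no value, "
                        f"got {param!r}"
                    )
                body = [copy_item(it) for it in definition.body]
                expand_value = definition.name
            expand_tag = HedTag(node=schema.get("Def-expand"), value=expand_value)
            return HedGroup([expand_tag] + body)
        return item
    return HedGroup([_expand_item(it, registry, schema) for it in item.items])


def expand_defs(
    hs: HedString, registry: DefinitionRegistry, schema: HedSchema
) -> HedString:
    """Replace every ``Def/Name`` with its ``(Def-expand/Name, <body>)``.

    Enclosing group structure is preserved; idempotent on its own output.
    """
    return HedString([_expand_item(it, registry, schema) for it in hs.items])


def _contract_item(item, schema: HedSchema):
    if isinstance(item, HedTag):
        return item
    expand_tags = [
        t for t in item.tags() if t.node.name.casefold() == "def-expand"
    ]
    if expand_tags and expand_tags[0].value is not None:
        return HedTag(node=schema.get("Def"), value=expand_tags[0].value)
    return HedGroup([_contract_item(it, schema) for it in item.items])


def contract_defs(hs: HedString, schema: HedSchema) -> HedString:
    """Inverse of :func:`expand_defs`: fold Def-expand groups back to Def."""
    return HedString([_contract_item(it, schema) for it in hs.items])
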