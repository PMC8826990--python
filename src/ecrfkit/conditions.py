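"""Skip-pattern / conditional-visibility grammar.

A condition is a conjunction of comparison clauses::

    FIELD op literal [AND FIELD op literal]...

with ``op`` one of ``= != < <= > >= IN``; ``IN`` takes a parenthesized,
comma-separated literal list.  The grammar is deliberately AND-only with
no nesting, which keeps skip logic decidable and lets the configuration
checker verify that every referenced field precedes its dependent.

Clauses are typed against the referenced field's data type when a
revision is available (numeric fields compare numerically, text and date
fields lexicographically — ISO dates order correctly as strings).  At
evaluation time a raw value that cannot be coerced to the field's type
makes the clause false rather than raising, so data entry can never
deadlock on a half-typed parent value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

from .errors import ConfigParseError

OPERATORS = ("!=", "<=", ">=", "=", "<", ">", "IN")

Literal = Union[float, str]

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<op><=|>=|!=|=|<|>)
      | (?P<kw>\bAND\b|\bIN\b)
      | (?P<lparen>\()
      | (?P<rparen>\))
      | (?P<comma>,)
      | (?P<quoted>'[^']*'|"[^"]*")
      | (?P<bare>[^\s()=<>!,]+)
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise ConfigParseError(f"condition {text!r}: cannot tokenize at {text[pos:]!r}")
        pos = m.end()
        for kind in ("op", "kw", "lparen", "rparen", "comma", "quoted", "bare"):
            val = m.group(kind)
            if val is not None:
                tokens.append((kind, val))
                break
    return tokens


@dataclass(frozen=True)
class Clause:
    field_name: str
    op: str
    value: Union[Literal, tuple[Literal, ...]]  # tuple only for IN

    def evaluate(self, raw: Optional[str], numeric: bool) -> bool:
        """Truth of this clause against a raw value (None = unanswered)."""
        if raw is None or raw == "":
            return False
        if numeric:
            try:
                actual: Literal = float(raw)
            except (TypeError, ValueError):
                return False
        else:
            actual = str(raw)
        if self.op == "IN":
            return actual in self.value  # type: ignore[operator]
        other = self.value
        if self.op == "=":
            return actual == other
        if self.op == "!=":
            return actual != other
        try:
            if self.op == "<":
                return actual < other  # type: ignore[operator]
            if self.op == "<=":
                return actual <= other  # type: ignore[operator]
            if self.op == ">":
                return actual > other  # type: ignore[operator]
            if self.op == ">=":
                return actual >= other  # type: ignore[operator]
        except TypeError:
            return False
        raise AssertionError(f"unknown operator {self.op}")


@dataclass(frozen=True)
class SkipCondition:
    clauses: tuple[Clause, ...]
    source: str = ""

    def referenced_fields(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.clauses:
            if c.field_name not in seen:
                seen.append(c.field_name)
        return tuple(seen)

    def evaluate(self, raw_values: Mapping[str, Optional[str]],
                 numeric_fields: frozenset[str]) -> bool:
        """All clauses true against the raw value map (AND semantics)."""
        return all(
            c.evaluate(raw_values.get(c.field_name), c.field_name in numeric_fields)
            for c in self.clauses
        )


def _strip_quotes(token: str) -> str:
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "'\"":
        return token[1:-1]
    return token


def _type_literal(token_kind: str, token: str, numeric: bool, source: str) -> Literal:
    raw = _strip_quotes(token) if token_kind == "quoted" else token
    if numeric:
        try:
            return float(raw)
        except ValueError:
            raise ConfigParseError(
                f"condition {source!r}: literal {raw!r} is not numeric"
            )
    return raw


def parse_condition(
    text: str,
    dtypes: Optional[Mapping[str, str]] = None,
) -> SkipCondition:
    """Parse a condition string into a typed clause conjunction.

    ``dtypes`` maps field names to their data type (T/N/D); when given,
    unknown field references and type-incompatible literals are rejected.
    Without it (workflow contexts), a literal is treated as numeric when
    it parses as a number.
    """
    tokens = _tokenize(text)
    clauses: list[Clause] = []
    i = 0
    while i < len(tokens):
        if clauses:
            kind, val = tokens[i]
            if not (kind == "kw" and val == "AND"):
                raise ConfigParseError(f"condition {text!r}: expected AND, got {val!r}")
            i += 1
        if i >= len(tokens) or tokens[i][0] not in ("bare", "quoted"):
            raise ConfigParseError(f"condition {text!r}: expected field name")
        field_name = _strip_quotes(tokens[i][1])
        i += 1
        if dtypes is not None and field_name not in dtypes:
            raise ConfigParseError(f"condition {text!r}: unknown field {field_name!r}")
        if i >= len(tokens):
            raise ConfigParseError(f"condition {text!r}: dangling field {field_name!r}")
        kind, op = tokens[i]
        if kind == "kw" and op == "IN":
            op = "IN"
        elif kind != "op":
            raise ConfigParseError(f"condition {text!r}: expected operator, got {op!r}")
        i += 1
        numeric = dtypes[field_name] == "N" if dtypes is not None else None

        if op == "IN":
            if i >= len(tokens) or tokens[i][0] != "lparen":
                raise ConfigParseError(f"condition {text!r}: IN requires '('")
            i += 1
            members: list[Literal] = []
            while i < len(tokens) and tokens[i][0] != "rparen":
                if tokens[i][0] == "comma":
                    i += 1
                    continue
                if tokens[i][0] not in ("bare", "quoted"):
                    raise ConfigParseError(f"condition {text!r}: bad IN member")
                members.append(_literal(tokens[i], numeric, text))
                i += 1
            if i >= len(tokens):
                raise ConfigParseError(f"condition {text!r}: unterminated IN list")
            i += 1  # consume ')'
            if not members:
                raise ConfigParseError(f"condition {text!r}: empty IN list")
            clauses.append(Clause(field_name, "IN", tuple(members)))
        else:
            if i >= len(tokens) or tokens[i][0] not in ("bare", "quoted"):
                raise ConfigParseError(f"condition {text!r}: dangling operator {op!r}")
            clauses.append(Clause(field_name, op, _literal(tokens[i], numeric, text)))
            i += 1
    if not clauses:
        raise ConfigParseError(f"condition {text!r}: empty")
    return SkipCondition(clauses=tuple(clauses), source=text)


def _literal(token: tuple[str, str], numeric: Optional[bool], source: str) -> Literal:
    kind, tok = token
    if numeric is None:
        # untyped context: numbers compare numerically when they parse
        raw = _strip_quotes(tok) if kind == "quoted" else tok
        if kind == "bare":
            try:
                return float(raw)
            except ValueError:
                return raw
        return raw
    return _type_literal(kind, tok, numeric, source)


def evaluate_context(condition: SkipCondition, context: Mapping[str, object]) -> bool:
    """Evaluate a condition against a flat name→value context (workflows).

    Values are stringified; a clause whose literal is numeric compares
    numerically, mirroring the typed evaluation path.
    """
    raw = {k: ("" if v is None else str(v)) for k, v in context.items()}
    numeric = frozenset(
        c.field_name
        for c in condition.clauses
        if isinstance(c.value, float)
        or (isinstance(c.value, tuple) and any(isinstance(m, float) for m in c.value))
    )
    return condition.evaluate(raw, numeric)
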