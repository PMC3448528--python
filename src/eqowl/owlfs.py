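"""Writer and parser for the emitted OWL 2 functional-style syntax subset.

The dialect covers exactly what the compiler produces: Prefix declarations,
``Declaration(Class(..))`` / ``Declaration(ObjectProperty(..))``,
``SubClassOf``, ``DisjointClasses`` (binary), and
``EquivalentClasses(NamedClass, expr)`` where expressions are built from
abbreviated IRIs, ``ObjectIntersectionOf`` and ``ObjectSomeValuesFrom``.
Anything else (unions, complements, datatypes, …) is a parse error.

The writer is canonical: prefixes sorted by name, declarations sorted by
CURIE, axioms sorted lexicographically within each kind.  ``parse(write(x))``
is structurally equal to ``x`` and ``write(parse(t))`` is byte-equal to
``t`` for canonical ``t``.
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional, Tuple

from .compile import DEFAULT_GEN_PREFIX, EmittedOntology
from .errors import OwlParseError
from .model import And, Atom, ClassExpr, PropRef, Some, Term

__all__ = ["write_ontology", "parse_ontology", "ontology_equal"]

DEFAULT_ONTOLOGY_IRI = "http://example.org/pheno/ontology"


# ---------------------------------------------------------------------------
# Writing


def _curie_of_prop(prop: PropRef, gen_prefix: str) -> str:
    return f"{gen_prefix}:{prop.name}" if prop.kind == "generated" else f":{prop.name}"


def _expr_text(expr: ClassExpr, gen_prefix: str) -> str:
    if isinstance(expr, Atom):
        return expr.term.curie
    if isinstance(expr, Some):
        return (
            "ObjectSomeValuesFrom("
            + _curie_of_prop(expr.prop, gen_prefix)
            + " "
            + _expr_text(expr.filler, gen_prefix)
            + ")"
        )
    if isinstance(expr, And):
        return (
            "ObjectIntersectionOf("
            + " ".join(_expr_text(c, gen_prefix) for c in expr.conjuncts)
            + ")"
        )
    raise TypeError(f"not a ClassExpr: {expr!r}")


def write_ontology(
    ontology: EmittedOntology,
    *,
    gen_prefix: str = DEFAULT_GEN_PREFIX,
    ontology_iri: str = DEFAULT_ONTOLOGY_IRI,
) -> str:
    """Serialize an :class:`EmittedOntology` to canonical text."""
    lines: List[str] = []
    for pfx in sorted(ontology.prefixes):
        lines.append(f"Prefix({pfx}:=<{ontology.prefixes[pfx]}>)")
    lines.append(f"Ontology(<{ontology_iri}>")
    for curie in sorted(ontology.declared_classes):
        lines.append(f"Declaration(Class({curie}))")
    for prop in sorted(ontology.declared_object_properties, key=lambda p: (p.kind, p.name)):
        lines.append(f"Declaration(ObjectProperty({_curie_of_prop(prop, gen_prefix)}))")
    lines.extend(sorted(f"SubClassOf({c} {p})" for c, p in ontology.subclass_axioms))
    lines.extend(sorted(f"DisjointClasses({a} {b})" for a, b in ontology.disjoint_axioms))
    lines.extend(
        sorted(
            f"EquivalentClasses({name} {_expr_text(expr, gen_prefix)})"
            for name, expr in ontology.named_class_definitions.items()
        )
    )
    lines.append(")")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Parsing

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<comment>\#[^\n]*)
  | (?P<iri><[^<>\s]*>)
  | (?P<pname>[A-Za-z_][A-Za-z0-9_.\-]*:[A-Za-z0-9_.\-]*|:[A-Za-z0-9_.\-]+)
  | (?P<keyword>[A-Za-z][A-Za-z0-9]*)
  | (?P<colon>:)
  | (?P<lpar>\()
  | (?P<rpar>\))
  | (?P<eq>=)
    """,
    re.VERBOSE,
)


class _Token:
    __slots__ = ("kind", "text", "line", "col")

    def __init__(self, kind: str, text: str, line: int, col: int):
        self.kind, self.text, self.line, self.col = kind, text, line, col


def _tokenize(text: str) -> List[_Token]:
    tokens: List[_Token] = []
    line, col = 1, 1
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise OwlParseError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup
        chunk = m.group()
        if kind not in ("ws", "comment"):
            tokens.append(_Token(kind, chunk, line, col))
        nl = chunk.count("\n")
        if nl:
            line += nl
            col = len(chunk) - chunk.rfind("\n")
        else:
            col += len(chunk)
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: List[_Token], gen_prefix: str):
        self.tokens = tokens
        self.pos = 0
        self.gen_prefix = gen_prefix

    def _err(self, message: str) -> OwlParseError:
        if self.pos < len(self.tokens):
            t = self.tokens[self.pos]
            return OwlParseError(message, t.line, t.col)
        last = self.tokens[-1] if self.tokens else None
        return OwlParseError(
            message, last.line if last else 1, (last.col + len(last.text)) if last else 1
        )

    def peek(self) -> Optional[_Token]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self, kind: str, text: Optional[str] = None) -> _Token:
        tok = self.peek()
        if tok is None or tok.kind != kind or (text is not None and tok.text != text):
            want = text or kind
            raise self._err(f"expected {want!r}")
        self.pos += 1
        return tok

    # -- grammar -----------------------------------------------------------

    def ontology(self) -> Tuple[EmittedOntology, str]:
        prefixes: Dict[str, str] = {}
        while self.peek() is not None and self.peek().text == "Prefix":
            self.take("keyword", "Prefix")
            self.take("lpar")
            tok = self.peek()
            if tok is None:
                raise self._err("expected prefix name")
            if tok.kind == "pname" and tok.text.endswith(":"):
                pfx = tok.text[:-1]
                self.pos += 1
            elif tok.kind == "colon":
                pfx = ""
                self.pos += 1
            else:
                raise self._err("expected prefix name")
            self.take("eq")
            iri = self.take("iri").text[1:-1]
            self.take("rpar")
            prefixes[pfx] = iri
        self.take("keyword", "Ontology")
        self.take("lpar")
        iri_tok = self.peek()
        ontology_iri = DEFAULT_ONTOLOGY_IRI
        if iri_tok is not None and iri_tok.kind == "iri":
            ontology_iri = iri_tok.text[1:-1]
            self.pos += 1
        classes: set = set()
        props: set = set()
        subclass: List[Tuple[str, str]] = []
        disjoint: List[Tuple[str, str]] = []
        definitions: Dict[str, ClassExpr] = {}
        while True:
            tok = self.peek()
            if tok is None:
                raise self._err("unterminated Ontology(...)")
            if tok.kind == "rpar":
                self.pos += 1
                break
            if tok.kind != "keyword":
                raise self._err("expected an axiom keyword")
            if tok.text == "Declaration":
                self.pos += 1
                self.take("lpar")
                what = self.take("keyword")
                self.take("lpar")
                curie = self._curie()
                self.take("rpar")
                self.take("rpar")
                if what.text == "Class":
                    classes.add(curie)
                elif what.text == "ObjectProperty":
                    props.add(self._prop_from_curie(curie))
                else:
                    raise OwlParseError(
                        f"unsupported declaration kind {what.text!r}", what.line, what.col
                    )
            elif tok.text == "SubClassOf":
                self.pos += 1
                self.take("lpar")
                c = self._curie()
                p = self._curie()
                self.take("rpar")
                subclass.append((c, p))
            elif tok.text == "DisjointClasses":
                self.pos += 1
                self.take("lpar")
                a = self._curie()
                b = self._curie()
                self.take("rpar")
                disjoint.append(tuple(sorted((a, b))))
            elif tok.text == "EquivalentClasses":
                self.pos += 1
                self.take("lpar")
                name = self._curie()
                expr = self._expr()
                self.take("rpar")
                if name in definitions:
                    raise OwlParseError(f"duplicate definition for {name}", tok.line, tok.col)
                definitions[name] = expr
            else:
                raise OwlParseError(
                    f"unsupported construct {tok.text!r}", tok.line, tok.col
                )
        if self.peek() is not None:
            raise self._err("trailing content after Ontology(...)")
        ontology = EmittedOntology(
            prefixes=prefixes,
            declared_classes=frozenset(classes),
            declared_object_properties=frozenset(props),
            named_class_definitions=definitions,
            subclass_axioms=tuple(sorted(subclass)),
            disjoint_axioms=tuple(sorted(disjoint)),
        )
        return ontology, ontology_iri

    def _curie(self) -> str:
        tok = self.peek()
        if tok is None or tok.kind != "pname":
            raise self._err("expected a CURIE")
        self.pos += 1
        return tok.text

    def _prop_from_curie(self, curie: str) -> PropRef:
        pfx, name = curie.split(":", 1)
        if pfx == "":
            return PropRef(name, "fixed")
        if pfx == self.gen_prefix:
            return PropRef(name, "generated")
        raise self._err(f"object property {curie} outside the fixed/generated namespaces")

    def _expr(self) -> ClassExpr:
        tok = self.peek()
        if tok is None:
            raise self._err("expected a class expression")
        if tok.kind == "pname":
            self.pos += 1
            return Atom(Term(tok.text))
        if tok.kind == "keyword" and tok.text == "ObjectIntersectionOf":
            self.pos += 1
            self.take("lpar")
            parts = []
            while self.peek() is not None and self.peek().kind != "rpar":
                parts.append(self._expr())
            self.take("rpar")
            if len(parts) < 2:
                raise OwlParseError(
                    "ObjectIntersectionOf needs >= 2 operands", tok.line, tok.col
                )
            return And(tuple(parts))
        if tok.kind == "keyword" and tok.text == "ObjectSomeValuesFrom":
            self.pos += 1
            self.take("lpar")
            prop = self._prop_from_curie(self._curie())
            filler = self._expr()
            self.take("rpar")
            return Some(prop, filler)
        raise OwlParseError(
            f"unsupported class-expression construct {tok.text!r}", tok.line, tok.col
        )


def parse_ontology(text: str, *, gen_prefix: str = DEFAULT_GEN_PREFIX) -> EmittedOntology:
    """Parse canonical-subset text back into an :class:`EmittedOntology`.

    Constructs outside the subset raise :class:`OwlParseError` with line and
    column.  Note that the textual form carries no term categories or
    labels, so parsed atoms are term stubs; use :func:`ontology_equal` for
    structural comparison.
    """
    parser = _Parser(_tokenize(text), gen_prefix)
    ontology, _ = parser.ontology()
    return ontology


def ontology_equal(a: EmittedOntology, b: EmittedOntology) -> bool:
    """Structural equality by IRIs and expression shape.

    Ignores term labels/categories (which the text format does not carry).
    """
    def defs(o: EmittedOntology) -> Dict[str, str]:
        return {name: expr.key() for name, expr in o.named_class_definitions.items()}

    return (
        a.prefixes == b.prefixes
        and a.declared_classes == b.declared_classes
        and a.declared_object_properties == b.declared_object_properties
        and tuple(sorted(a.subclass_axioms)) == tuple(sorted(b.subclass_axioms))
        and tuple(sorted(a.disjoint_axioms)) == tuple(sorted(b.disjoint_axioms))
        and defs(a) == defs(b)
    )
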