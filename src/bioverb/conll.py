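"""Reading and writing dependency-parsed corpora in CoNLL-X / CoNLL-U form.

Only the columns the pipeline consumes are modelled: surface form, lemma,
coarse POS, head index and dependency label.  Multiword-token and empty-node
lines of CoNLL-U (ids like ``1-2`` or ``1.1``) are skipped; comment lines
(``# ...``) may carry ``sent_id`` / ``doc_id`` metadata.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO


class ConllParseError(ValueError):
    """A malformed token line; message names the offending line number."""


class ConllStructureError(ValueError):
    """An ill-formed sentence (dangling head, no root); names the sentence."""


@dataclass(frozen=True)
class ParsedToken:
    """One token of a dependency parse.

    ``head`` is the 1-based index of the governing token, 0 for the root.
    """

    index: int
    form: str
    lemma: str
    pos: str
    head: int
    deprel: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"token index must be >= 1, got {self.index}")
        if self.head < 0:
            raise ValueError(f"head must be >= 0, got {self.head}")
        if self.head == self.index:
            raise ValueError(f"token {self.index} cannot head itself")
        if not self.deprel:
            raise ValueError("deprel must be non-empty")

    @property
    def norm(self) -> str:
        """Normalized word: lemma when present, else lowercased form."""
        return self.lemma if self.lemma else self.form.lower()


@dataclass
class ParsedSentence:
    """An ordered token sequence with head links; the unit of pair extraction."""

    tokens: list[ParsedToken]
    doc_id: str = ""
    sent_id: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    def validate(self) -> None:
        n = len(self.tokens)
        has_root = False
        for tok in self.tokens:
            if tok.head == 0:
                has_root = True
            elif tok.head > n:
                raise ConllStructureError(
                    f"sentence {self.sent_id or '?'}: token {tok.index} has "
                    f"dangling head {tok.head} (only {n} tokens)"
                )
        if n and not has_root:
            raise ConllStructureError(
                f"sentence {self.sent_id or '?'}: no token has head 0"
            )

    def arcs(self) -> Iterator[tuple[ParsedToken, ParsedToken, str]]:
        """Yield (head_token, dependent_token, deprel) for non-root arcs."""
        for tok in self.tokens:
            if tok.head > 0:
                yield self.tokens[tok.head - 1], tok, tok.deprel


# column positions (0-based): form, lemma, pos, head, deprel
_DIALECT_COLUMNS = {
    # CoNLL-X: ID FORM LEMMA CPOSTAG POSTAG FEATS HEAD DEPREL PHEAD PDEPREL
    "conllx": (1, 2, 3, 6, 7),
    # CoNLL-U: ID FORM LEMMA UPOS XPOS FEATS HEAD DEPREL DEPS MISC
    "conllu": (1, 2, 3, 6, 7),
}


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, encoding="utf-8")


def read_parsed_corpus(
    path: str | Path, dialect: str = "conllu"
) -> Iterator[ParsedSentence]:
    """Stream sentences from a CoNLL file (plain or gzip) in file order.

    Raises :class:`ConllParseError` naming the line number on a malformed
    line and :class:`ConllStructureError` on a dangling head index.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}; use 'conllx' or 'conllu'")
    with _open_text(path) as handle:
        yield from _parse_stream(handle, dialect)


def _parse_stream(handle: Iterable[str], dialect: str) -> Iterator[ParsedSentence]:
    i_form, i_lemma, i_pos, i_head, i_deprel = _DIALECT_COLUMNS[dialect]
    tokens: list[ParsedToken] = []
    doc_id = ""
    sent_id = ""
    n_sent = 0

    def flush() -> Iterator[ParsedSentence]:
        nonlocal tokens, sent_id, n_sent
        if tokens:
            n_sent += 1
            sent = ParsedSentence(
                tokens=tokens, doc_id=doc_id, sent_id=sent_id or str(n_sent)
            )
            sent.validate()
            tokens = []
            sent_id = ""
            yield sent

    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            yield from flush()
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("sent_id"):
                sent_id = body.split("=", 1)[-1].strip()
            elif body.startswith("doc_id") or body.startswith("newdoc id"):
                doc_id = body.split("=", 1)[-1].strip()
            continue
        cols = line.split("\t")
        if len(cols) < max(i_head, i_deprel) + 1:
            raise ConllParseError(
                f"line {lineno}: expected >= {max(i_head, i_deprel) + 1} "
                f"tab-separated columns, got {len(cols)}"
            )
        tok_id = cols[0]
        if "-" in tok_id or "." in tok_id:  # multiword range / empty node
            continue
        try:
            index = int(tok_id)
            head = int(cols[i_head])
        except ValueError as exc:
            raise ConllParseError(f"line {lineno}: non-integer id or head") from exc
        lemma = cols[i_lemma]
        if lemma == "_":
            lemma = ""
        try:
            token = ParsedToken(
                index=index,
                form=cols[i_form],
                lemma=lemma,
                pos=cols[i_pos],
                head=head,
                deprel=cols[i_deprel],
            )
        except ValueError as exc:
            raise ConllParseError(f"line {lineno}: {exc}") from exc
        if index != len(tokens) + 1:
            raise ConllParseError(
                f"line {lineno}: token index {index} not contiguous "
                f"(expected {len(tokens) + 1})"
            )
        tokens.append(token)
    yield from flush()


def write_conll(
    sentences: Iterable[ParsedSentence], path: str | Path, dialect: str = "conllu"
) -> int:
    """Write sentences in CoNLL form; returns the number written."""
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    n = 0
    with open(path, "w", encoding="utf-8") as out:
        for sent in sentences:
            if sent.sent_id:
                out.write(f"# sent_id = {sent.sent_id}\n")
            for tok in sent.tokens:
                cols = ["_"] * 10
                cols[0] = str(tok.index)
                cols[1] = tok.form
                cols[2] = tok.lemma or "_"
                cols[3] = tok.pos
                cols[4] = tok.pos
                cols[6] = str(tok.head)
                cols[7] = tok.deprel
                out.write("\t".join(cols) + "\n")
            out.write("\n")
            n += 1
    return n
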