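"""Genes, extremities, adjacencies and genomes.

A genome is a set of linear or circular chromosomes over signed genes.  Each
gene ``g`` has two extremities, the tail ``g_t`` and the head ``g_h``; a gene
written ``+g`` points tail-to-head, ``-g`` head-to-tail.  Two consecutive gene
ends form an *adjacency*, represented here as an unordered pair (frozenset) of
extremities; each end of a linear chromosome is completed with a *null
extremity* (a "cap") so that every chromosome end is also an ordinary
adjacency.  A linear chromosome with n genes therefore contributes n + 1
adjacencies, a circular chromosome n adjacencies, and a genome with all-
distinct genes is uniquely encoded by its adjacency set.

Duplicated genes are distinguished from their originals by a copy index,
serialised with prime suffixes: ``2`` is the original, ``2'`` the first copy,
``2''`` the second, and so on.

Null extremities carry a per-instance ``cap_id`` so that distinct telomeres
remain distinct objects inside a trajectory graph; content-level genome
comparison strips the cap ids (see :func:`content_key`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .errors import (
    DuplicateGeneError,
    InvalidAdjacencySetError,
    ParseError,
)

HEAD = "h"
TAIL = "t"
NULL = "0"


@dataclass(frozen=True, order=True)
class GeneId:
    """A gene family plus a copy index (0 = original, k >= 1 = k-th duplicate)."""

    family: str
    copy: int = 0

    def __post_init__(self):
        if not self.family:
            raise ValueError("gene family must be non-empty")
        if self.copy < 0:
            raise ValueError("copy index must be non-negative")

    @property
    def label(self) -> str:
        return self.family + "'" * self.copy

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class Extremity:
    """A gene end (head/tail) or a null extremity capping a linear chromosome."""

    kind: str  # HEAD, TAIL or NULL
    gene: Optional[GeneId] = None
    cap_id: Optional[int] = None

    def __post_init__(self):
        if self.kind == NULL:
            if self.gene is not None:
                raise ValueError("null extremity carries no gene")
        elif self.kind in (HEAD, TAIL):
            if self.gene is None:
                raise ValueError("gene extremity needs a gene")
            if self.cap_id is not None:
                raise ValueError("only null extremities carry cap ids")
        else:
            raise ValueError(f"bad extremity kind {self.kind!r}")

    @property
    def is_null(self) -> bool:
        return self.kind == NULL

    def sort_key(self):
        if self.is_null:
            return (1, "", -1, "", self.cap_id if self.cap_id is not None else -1)
        return (0, self.gene.family, self.gene.copy, self.kind, -1)

    def token(self) -> str:
        """Serialise as e.g. ``2'_h`` or ``0#3``."""
        if self.is_null:
            return f"0#{self.cap_id}" if self.cap_id is not None else "0"
        return f"{self.gene.label}_{self.kind}"

    def __str__(self) -> str:
        return self.token()

    def __repr__(self) -> str:
        return f"Extremity({self.token()})"


def head(gene: GeneId) -> Extremity:
    return Extremity(HEAD, gene)


def tail(gene: GeneId) -> Extremity:
    return Extremity(TAIL, gene)


def null_extremity(cap_id: Optional[int] = None) -> Extremity:
    return Extremity(NULL, cap_id=cap_id)


@dataclass(frozen=True, order=True)
class SignedGene:
    """A gene occurrence with reading orientation along its chromosome."""

    gene: GeneId
    sign: int  # +1 or -1

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")

    @property
    def left(self) -> Extremity:
        """The extremity first met when reading the gene in chromosome order."""
        return tail(self.gene) if self.sign == 1 else head(self.gene)

    @property
    def right(self) -> Extremity:
        return head(self.gene) if self.sign == 1 else tail(self.gene)

    def reverse(self) -> "SignedGene":
        return SignedGene(self.gene, -self.sign)

    def token(self) -> str:
        return ("-" if self.sign == -1 else "") + self.gene.label

    def __str__(self) -> str:
        return self.token()


# An adjacency *content* is just a frozenset of one or two extremities.  The
# frozenset view makes (a, b) and (-b, -a) the same value automatically.
Adjacency = frozenset


def adjacency(*extremities: Extremity) -> Adjacency:
    a = frozenset(extremities)
    if not 1 <= len(a) <= 2:
        raise ValueError("an adjacency has one or two distinct extremities")
    return a


def adjacency_between(a: SignedGene, b: SignedGene) -> Adjacency:
    """The adjacency joining consecutive signed genes ``a b``: {right(a), left(b)}."""
    return adjacency(a.right, b.left)


def canonicalize(adj: Iterable[Extremity]) -> Adjacency:
    """Canonical (frozenset) form of an extremity pair."""
    return adjacency(*adj)


def is_null_null(adj: Adjacency) -> bool:
    return all(e.is_null for e in adj)


def content_key(adj: Adjacency) -> frozenset:
    """Cap-insensitive content of an adjacency (null caps erased)."""
    return frozenset(null_extremity() if e.is_null else e for e in adj)


def adjacency_token(adj: Adjacency) -> str:
    """Serialise an adjacency as ``{a,b}`` with extremities in sort order."""
    return "{" + ",".join(e.token() for e in sorted(adj, key=Extremity.sort_key)) + "}"


def sorted_adjacencies(adjs: Iterable[Adjacency]) -> list:
    """Deterministic ordering of adjacency contents (never rely on set order)."""
    return sorted(adjs, key=adjacency_token)


@dataclass(frozen=True)
class Chromosome:
    genes: tuple
    circular: bool = False

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError("empty chromosomes are not supported")

    def __len__(self) -> int:
        return len(self.genes)

    def token(self) -> str:
        end = "@" if self.circular else "$"
        return " ".join(g.token() for g in self.genes) + " " + end

    def reverse(self) -> "Chromosome":
        return Chromosome(tuple(g.reverse() for g in reversed(self.genes)), self.circular)

    def rotate(self, k: int) -> "Chromosome":
        if not self.circular:
            raise ValueError("only circular chromosomes rotate")
        g = self.genes
        k %= len(g)
        return Chromosome(g[k:] + g[:k], True)


class Genome:
    """A list of chromosomes; equality and hashing are content-based.

    :meth:`adjacencies` derives the adjacency set, assigning fresh sequential
    cap ids (1, 2, ...) to the null extremities of linear chromosome ends in
    chromosome order.  The assignment is deterministic, so two calls agree.
    """

    def __init__(self, chromosomes: Iterable[Chromosome]):
        self.chromosomes = list(chromosomes)
        seen = set()
        for chrom in self.chromosomes:
            for sg in chrom.genes:
                if sg.gene in seen:
                    raise DuplicateGeneError(f"gene {sg.gene} occurs twice")
                seen.add(sg.gene)

    def genes(self) -> Iterator[GeneId]:
        for chrom in self.chromosomes:
            for sg in chrom.genes:
                yield sg.gene

    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def adjacencies(self) -> list:
        """Adjacency multiset of the genome (a list of frozenset contents)."""
        out = []
        cap = 0
        for chrom in self.chromosomes:
            g = chrom.genes
            for i in range(len(g) - 1):
                out.append(adjacency_between(g[i], g[i + 1]))
            if chrom.circular:
                out.append(adjacency_between(g[-1], g[0]))
            else:
                cap += 1
                out.append(adjacency(null_extremity(cap), g[0].left))
                cap += 1
                out.append(adjacency(g[-1].right, null_extremity(cap)))
        return out

    # -- comparison helpers -------------------------------------------------

    def content_multiset(self) -> dict:
        """Cap-insensitive adjacency content -> multiplicity."""
        counts: dict = {}
        for a in self.adjacencies():
            k = content_key(a)
            counts[k] = counts.get(k, 0) + 1
        return counts

    def canonical(self) -> tuple:
        """Canonical form: invariant under chromosome order, reversal, rotation."""
        forms = []
        for chrom in self.chromosomes:
            cands = [chrom, chrom.reverse()]
            if chrom.circular:
                cands = [c.rotate(k) for c in cands for k in range(len(c))]
            forms.append(min(c.token() for c in cands))
        return tuple(sorted(forms))

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def __repr__(self) -> str:
        return f"Genome({' ; '.join(c.token() for c in self.chromosomes)})"


# ---------------------------------------------------------------------------
# GRIMM-dialect text I/O
#
#   >name            optional header line
#   1 -2 3' 4 $      one chromosome per line; '$' linear, '@' circular
#   # comment        comments and blank lines ignored
# ---------------------------------------------------------------------------

_GENE_RE = re.compile(r"^(-?)(\d+)('*)$")


def _parse_gene_token(tok: str, lineno: int, col: int) -> SignedGene:
    m = _GENE_RE.match(tok)
    if not m:
        raise ParseError(f"bad gene token {tok!r}", line=lineno, column=col)
    sign = -1 if m.group(1) else 1
    return SignedGene(GeneId(m.group(2), len(m.group(3))), sign)


def parse_genomes(text: str) -> list:
    """Parse a GRIMM-dialect file, returning ``[(name, Genome), ...]``."""
    genomes = []
    name = None
    chroms: list = []
    started = False

    def flush():
        nonlocal chroms, name
        if started:
            if not chroms:
                raise ParseError(f"genome {name!r} has no chromosomes")
            genomes.append((name, Genome(chroms)))
        chroms = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            started = True
            continue
        started = True
        toks = line.split()
        if toks[-1] not in ("$", "@"):
            raise ParseError("chromosome line must end with '$' or '@'", line=lineno)
        genes = tuple(
            _parse_gene_token(t, lineno, i + 1) for i, t in enumerate(toks[:-1])
        )
        if not genes:
            raise ParseError("empty chromosome", line=lineno)
        chroms.append(Chromosome(genes, circular=(toks[-1] == "@")))
    flush()
    return genomes


def parse_genome(text: str) -> Genome:
    """Parse text containing exactly one genome."""
    genomes = parse_genomes(text)
    if len(genomes) != 1:
        raise ParseError(f"expected exactly one genome, found {len(genomes)}")
    return genomes[0][1]


def serialize_genome(genome: Genome, name: str = "genome") -> str:
    lines = [f">{name}"]
    lines.extend(c.token() for c in genome.chromosomes)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Adjacency set -> genome reconstruction
# ---------------------------------------------------------------------------


def genome_to_adjacencies(genome: Genome) -> list:
    return genome.adjacencies()


def adjacencies_to_genome(adjs: Iterable[Adjacency]) -> Genome:
    """Reconstruct a genome by walking extremity links.

    Raises :class:`InvalidAdjacencySetError` if a non-null extremity occurs
    in more than one adjacency, lacks its partner end, or a both-null
    adjacency (an "empty linear chromosome") is present.
    """
    adjs = list(adjs)
    by_ext: dict = {}
    for idx, a in enumerate(adjs):
        if is_null_null(a):
            raise InvalidAdjacencySetError(
                "both-null adjacency cannot be realised as a chromosome"
            )
        for e in a:
            if not e.is_null:
                if e in by_ext:
                    raise InvalidAdjacencySetError(f"extremity {e} occurs twice")
                by_ext[e] = idx

    def other_end(idx: int, e: Extremity) -> Extremity:
        a = adjs[idx]
        rest = [x for x in a if x != e]
        if not rest:  # single-extremity or degenerate pair
            raise InvalidAdjacencySetError(f"adjacency {adjacency_token(a)} malformed")
        return rest[0]

    def partner(e: Extremity) -> Extremity:
        return Extremity(HEAD if e.kind == TAIL else TAIL, e.gene)

    visited = set()
    chroms = []

    def walk(start_idx: int, first: Extremity, circular: bool) -> Chromosome:
        genes = []
        idx, e = start_idx, first
        while True:
            visited.add(idx)
            # entering gene via extremity e: sign + if e is its tail
            sg = SignedGene(e.gene, 1 if e.kind == TAIL else -1)
            genes.append(sg)
            nxt = partner(e)
            if nxt not in by_ext:
                raise InvalidAdjacencySetError(f"extremity {nxt} has no adjacency")
            idx = by_ext[nxt]
            if circular and idx == start_idx:
                break
            if idx in visited and not circular:
                raise InvalidAdjacencySetError("inconsistent linkage")
            e2 = other_end(idx, nxt)
            if e2.is_null:
                if circular:
                    raise InvalidAdjacencySetError("null extremity inside a cycle")
                visited.add(idx)
                break
            e = e2
            if circular and idx in visited:
                break
        return Chromosome(tuple(genes), circular)

    # linear chromosomes first: start from null-containing adjacencies in
    # deterministic order
    null_adjs = sorted(
        (i for i, a in enumerate(adjs) if any(e.is_null for e in a)),
        key=lambda i: adjacency_token(adjs[i]),
    )
    for i in null_adjs:
        if i in visited:
            continue
        start = next(e for e in adjs[i] if not e.is_null)
        chroms.append(walk(i, start, circular=False))

    # remaining adjacencies form circular chromosomes
    remaining = sorted(
        (i for i in range(len(adjs)) if i not in visited),
        key=lambda i: adjacency_token(adjs[i]),
    )
    for i in remaining:
        if i in visited:
            continue
        start = min(adjs[i], key=Extremity.sort_key)
        chroms.append(walk(i, start, circular=True))

    genome = Genome(chroms)
    if len(by_ext) != 2 * genome.n_genes():
        raise InvalidAdjacencySetError("dangling extremities")  # pragma: no cover
    return genome
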