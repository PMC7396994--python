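"""Multi-k de Bruijn graph assembly with trusted/untrusted contig seeding.

The assembler reconstructs a single deep-coverage amplicon, so it is built
for correctness and determinism rather than genome scale: k-mers from both
read strands are counted as-is (no canonicalization) and the two strands of
the graph are kept mirror-symmetric through every simplification step;
reverse-complement twins are collapsed only when contigs are emitted.

Trust semantics: k-mers of *trusted* contigs are exempt from the coverage
prune and always present in the graph; k-mers of *untrusted* contigs add a
pseudo-count of one and survive only where read support (plus that
pseudo-count) clears the threshold. Iterating k from small to large and
feeding each round's contigs to the next as untrusted input lets small-k
connectivity seed large-k resolution of the repeat tract.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib

from .reference import revcomp

DEFAULT_K_LIST = (21, 33, 55, 77, 99, 127)


@dataclass
class KmerTable:
    """Occurrence counts of every k-length window on both read strands."""

    k: int
    counts: Counter

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class AssemblyParams:
    k_list: tuple[int, ...] = DEFAULT_K_LIST
    min_kmer_count: int = 3
    trusted_contigs: tuple[str, ...] = ()
    untrusted_contigs: tuple[str, ...] = ()
    tip_length_factor: Optional[int] = None  # bases; None -> 2 * k
    bubble_max_divergence: int = 3

    def __post_init__(self) -> None:
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")
        if any(k % 2 == 0 for k in self.k_list):
            raise ValueError("k values must be odd")
        if tuple(sorted(self.k_list)) != tuple(self.k_list):
            raise ValueError("k_list must ascend")

    def tip_length(self, k: int) -> int:
        return 2 * k if self.tip_length_factor is None else self.tip_length_factor


@dataclass(frozen=True)
class Contig:
    """An assembled sequence with its SPAdes-style provenance header."""

    id: str
    seq: str
    mean_cov: float

    @property
    def length(self) -> int:
        return len(self.seq)


def make_contig(index: int, seq: str, mean_cov: float) -> Contig:
    return Contig(
        id=f"NODE_{index}_length_{len(seq)}_cov_{mean_cov:.2f}",
        seq=seq,
        mean_cov=mean_cov,
    )


def parse_contig_id(header: str) -> tuple[int, int, float]:
    """``(index, length, cov)`` from a ``NODE_i_length_L_cov_C`` header."""
    parts = header.split("_")
    try:
        return int(parts[1]), int(parts[3]), float(parts[5])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"not a NODE_i_length_L_cov_C header: {header!r}") from exc


def count_kmers(reads: Iterable[str], k: int) -> KmerTable:
    """Count every k-window of every read and of its reverse complement.

    Reads shorter than ``k`` are skipped. ``k`` must be odd and at least 11
    (shorter k values make the purine-rich amplicon graph collapse into
    near-complete tangles and are rejected outright).
    """
    if k % 2 == 0 or k < 11:
        raise ValueError(f"k must be odd and >= 11, got {k}")
    counts: Counter = Counter()
    for read in reads:
        n = len(read)
        if n < k:
            continue
        for seq in (read, revcomp(read)):
            counts.update([seq[i : i + k] for i in range(n - k + 1)])
    return KmerTable(k=k, counts=counts)


@dataclass
class DeBruijnGraph:
    """Edge-centric de Bruijn graph: edges are k-mers, nodes (k-1)-mers."""

    k: int
    edges: dict  # kmer -> count (float; includes untrusted pseudo-counts)
    trusted_edges: set = field(default_factory=set)

    def remove(self, kmers: Iterable[str]) -> None:
        for km in kmers:
            self.edges.pop(km, None)
            self.trusted_edges.discard(km)
            rc = revcomp(km)
            self.edges.pop(rc, None)
            self.trusted_edges.discard(rc)


def _contig_kmers(contigs: Sequence[str], k: int) -> set:
    out: set = set()
    for seq in contigs:
        for s in (seq, revcomp(seq)):
            out.update(s[i : i + k] for i in range(len(s) - k + 1))
    return out


def build_graph(table: KmerTable, params: AssemblyParams) -> DeBruijnGraph:
    """Apply the coverage prune with trusted-contig exemption.

    Read k-mers below ``min_kmer_count`` are dropped unless they occur in a
    trusted contig; untrusted-contig k-mers contribute a pseudo-count of one
    and remain subject to the prune.
    """
    k = table.k
    trusted = _contig_kmers(params.trusted_contigs, k)
    untrusted = _contig_kmers(params.untrusted_contigs, k)
    edges: dict = {}
    minc = params.min_kmer_count
    for km, c in table.counts.items():
        eff = c + (1 if km in untrusted else 0)
        if eff >= minc or km in trusted:
            edges[km] = eff
    for km in untrusted:
        if km not in edges:
            eff = table.counts.get(km, 0) + 1
            if eff >= minc or km in trusted:
                edges[km] = eff
    for km in trusted:
        if km not in edges:
            edges[km] = max(table.counts.get(km, 0), 1)
    return DeBruijnGraph(k=k, edges=edges, trusted_edges=trusted & set(edges))


def _adjacency(edges: dict):
    out = defaultdict(list)
    inc = defaultdict(list)
    for km in edges:
        out[km[:-1]].append(km)
        inc[km[1:]].append(km)
    return out, inc


def _unitigs(graph: DeBruijnGraph):
    """Maximal non-branching edge paths, as lists of k-mers."""
    out, inc = _adjacency(graph.edges)
    visited: set = set()
    paths: list[list[str]] = []

    def walk(start_kmer: str) -> list[str]:
        path = [start_kmer]
        visited.add(start_kmer)
        node = start_kmer[1:]
        while len(out[node]) == 1 and len(inc[node]) == 1:
            nxt = out[node][0]
            if nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            node = nxt[1:]
        return path

    for km in graph.edges:
        u = km[:-1]
        if len(out[u]) != 1 or len(inc[u]) != 1:
            if km not in visited:
                paths.append(walk(km))
    for km in graph.edges:  # leftover simple cycles
        if km not in visited:
            paths.append(walk(km))
    return paths, out, inc


def _path_seq(path: list[str]) -> str:
    return path[0] + "".join(km[-1] for km in path[1:])


def _path_cov(graph: DeBruijnGraph, path: list[str]) -> float:
    return sum(graph.edges[km] for km in path if km in graph.edges) / max(len(path), 1)


def _clip_tips(graph: DeBruijnGraph, tip_len: int) -> bool:
    """Remove short dead-end branches that are dominated at their junction.

    A genuine amplicon terminus is also a dead end, so length alone cannot
    decide: a tip is clipped only when a *higher-coverage* alternative branch
    enters (or leaves) the same junction — the low-coverage error branch
    loses, the true terminal path survives regardless of its length.
    """
    paths, out, inc = _unitigs(graph)
    removed = False
    for path in paths:
        seq = _path_seq(path)
        if len(seq) >= tip_len:
            continue
        if any(km not in graph.edges for km in path):
            continue  # already removed via a reverse-complement twin
        start_node, end_node = path[0][:-1], path[-1][1:]
        dead_start = len(inc[start_node]) == 0
        dead_end = len(out[end_node]) == 0
        if dead_start and dead_end:
            continue  # isolated fragment, not a tip off a junction
        tip_cov = _path_cov(graph, path)
        if dead_start and len(inc[end_node]) > 1:
            rivals = [
                graph.edges[e] for e in inc[end_node] if e != path[-1] and e in graph.edges
            ]
            if rivals and max(rivals) > tip_cov:
                graph.remove(path)
                removed = True
        elif dead_end and len(out[start_node]) > 1:
            rivals = [
                graph.edges[e] for e in out[start_node] if e != path[0] and e in graph.edges
            ]
            if rivals and max(rivals) > tip_cov:
                graph.remove(path)
                removed = True
    return removed


def _pop_bubbles(graph: DeBruijnGraph, max_div: int) -> bool:
    paths, out, inc = _unitigs(graph)
    by_ends: dict = defaultdict(list)
    for path in paths:
        by_ends[(path[0][:-1], path[-1][1:])].append(path)
    removed = False
    for (u, v), branches in by_ends.items():
        if len(branches) < 2 or u == v:
            continue
        scored = sorted(
            branches,
            key=lambda p: (-_path_cov(graph, p), _path_seq(p)),
        )
        keep = scored[0]
        keep_seq = _path_seq(keep)
        for other in scored[1:]:
            seq = _path_seq(other)
            d = edlib.align(seq, keep_seq, task="distance", k=max_div)["editDistance"]
            if d != -1 and all(km in graph.edges for km in other):
                graph.remove(other)
                removed = True
    return removed


def simplify_and_extract(graph: DeBruijnGraph, params: AssemblyParams) -> list[Contig]:
    """Clip tips, pop small bubbles, and emit unitigs as contigs.

    Bubble branches diverging by at most ``bubble_max_divergence`` edits are
    collapsed onto the higher-coverage branch (ties broken lexicographically).
    Contigs are reverse-complement deduplicated and emitted in descending
    (length, coverage) order with SPAdes-style ``NODE`` identifiers.
    """
    if not graph.edges:
        return []
    tip_len = params.tip_length(graph.k)
    for _ in range(100):
        changed = _clip_tips(graph, tip_len)
        changed |= _pop_bubbles(graph, params.bubble_max_divergence)
        if not changed:
            break
    paths, _, _ = _unitigs(graph)
    best: dict[str, float] = {}
    for path in paths:
        seq = _path_seq(path)
        canon = min(seq, revcomp(seq))
        cov = _path_cov(graph, path)
        if canon not in best or cov > best[canon]:
            best[canon] = cov
    ordered = sorted(best.items(), key=lambda kv: (-len(kv[0]), -kv[1], kv[0]))
    return [make_contig(i + 1, seq, cov) for i, (seq, cov) in enumerate(ordered)]


def assemble_multi_k(
    reads: Sequence[str],
    params: AssemblyParams,
    kmer_cache: Optional[dict] = None,
) -> list[Contig]:
    """Iterate k ascending, feeding each round's contigs forward as untrusted.

    Externally supplied trusted/untrusted contigs participate at every k; the
    contig list of the final k is returned. ``kmer_cache`` (k -> KmerTable)
    lets repeated assemblies of the same read set skip recounting.
    """
    reads = [r for r in reads if r]
    if not reads and not params.trusted_contigs:
        return []
    contigs: list[Contig] = []
    for k in params.k_list:
        if kmer_cache is not None and k in kmer_cache:
            table = kmer_cache[k]
        else:
            table = count_kmers(reads, k)
            if kmer_cache is not None:
                kmer_cache[k] = table
        round_params = AssemblyParams(
            k_list=(k,),
            min_kmer_count=params.min_kmer_count,
            trusted_contigs=params.trusted_contigs,
            untrusted_contigs=tuple(params.untrusted_contigs)
            + tuple(c.seq for c in contigs),
            tip_length_factor=params.tip_length_factor,
            bubble_max_divergence=params.bubble_max_divergence,
        )
        graph = build_graph(table, round_params)
        new = simplify_and_extract(graph, round_params)
        if new:
            contigs = new
    return contigs
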