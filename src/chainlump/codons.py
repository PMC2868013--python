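"""Genetic-code knowledge and the codon-substitution analysis pipeline.

Codon substitution is modeled as a Markov chain over the 61 sense codons
(stop codons carry no outgoing substitutions and are removed).  Grouping
codons by the amino acid they encode — with each group split into its
connected components under single point mutations — yields the code
partition; serine is the only amino acid whose codons are not connected by
single point mutations, so it splits into {TCT, TCC, TCA, TCG} and
{AGT, AGC}, giving 21 blocks in the standard code.

``analyze`` runs the full pipeline on a codon chain: spectrum and spectral
gap, spectral aggregations, amino-acid-level agglomeration (on the lumped
codon chain), most-significant aggregation, and Newick/JSON exports.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .agglomerate import MergeTrace, agglomerate, most_significant, to_newick
from .errors import InvalidGeneticCode, UnknownCodonLabel
from .lumpability import TAU_EMPIRICAL, is_lumpable
from .markov import (
    Partition,
    TransitionMatrix,
    lump,
    read_labeled_matrix,
    restrict,
    stationary_distribution,
)
from .spectral import cluster_elements, detect_gap, spectrum

logger = logging.getLogger(__name__)

STOP = "*"

#: The standard genetic code (NCBI translation table 1), DNA alphabet.
STANDARD_CODE_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": STOP, "TAG": STOP,
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": STOP, "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map over the 64 triplets (DNA alphabet)."""

    codon_to_aa: dict

    def __post_init__(self):
        c2a = {str(c).upper().replace("U", "T"): str(a) for c, a in self.codon_to_aa.items()}
        object.__setattr__(self, "codon_to_aa", c2a)
        if len(c2a) != 64:
            raise InvalidGeneticCode(f"{len(c2a)} codons in table, expected 64")
        bad = [c for c in c2a if len(c) != 3 or set(c) - set("TCAG")]
        if bad:
            raise InvalidGeneticCode(f"malformed codons {bad[:3]}")
        if not any(a == STOP for a in c2a.values()):
            raise InvalidGeneticCode("no stop codons in table")

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls(dict(STANDARD_CODE_TABLE))

    @classmethod
    def from_tsv(cls, path) -> "GeneticCode":
        """Read a 2-column codon<TAB>amino-acid table ('*' marks stops)."""
        table = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            codon, aa = line.split()[:2]
            table[codon] = aa
        return cls(table)

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, a in self.codon_to_aa.items() if a == STOP)

    @property
    def sense_codons(self) -> frozenset:
        return frozenset(c for c, a in self.codon_to_aa.items() if a != STOP)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon.upper().replace("U", "T")]


@dataclass(frozen=True)
class CodonChain:
    """A substitution chain over sense codons, paired with its genetic code."""

    matrix: TransitionMatrix
    code: GeneticCode

    def __post_init__(self):
        unknown = set(self.matrix.labels) - self.code.sense_codons
        if unknown:
            raise UnknownCodonLabel(f"labels {sorted(unknown)[:5]} are not sense codons")


def read_codon_matrix(
    path,
    delimiter: str = "\t",
    code: GeneticCode | None = None,
    tol_stochastic: float = 1e-6,
) -> CodonChain:
    """Read a labeled codon substitution matrix (TSV by default).

    Labels may use the RNA alphabet (U is transliterated to T).  Stop-codon
    rows and columns, if present, are removed by restriction with a logged
    warning; the remaining rows are renormalized.
    """
    if code is None:
        code = GeneticCode.standard()
    T = read_labeled_matrix(path, delimiter=delimiter, tol_stochastic=tol_stochastic)
    labels = tuple(l.upper().replace("U", "T") for l in T.labels)
    unknown = set(labels) - set(code.codon_to_aa)
    if unknown:
        raise UnknownCodonLabel(f"labels {sorted(unknown)[:5]} are not codons")
    T = TransitionMatrix(labels, T.P)
    stops = set(labels) & code.stop_codons
    if stops:
        logger.warning("removing %d stop codons from matrix: %s", len(stops), sorted(stops))
        T = restrict(T, set(labels) - stops)
    return CodonChain(T, code)


def hamming_components(codons) -> list[frozenset]:
    """Connected components of the Hamming-distance-1 graph over codons.

    Components are ordered by decreasing size, then by smallest codon, so
    the output is independent of the input ordering.
    """
    todo = {str(c).upper() for c in codons}
    if not todo:
        raise ValueError("empty codon set")
    comps = []
    while todo:
        stack = [min(todo)]
        todo.discard(stack[0])
        comp = set()
        while stack:
            u = stack.pop()
            comp.add(u)
            for v in list(todo):
                if sum(a != b for a, b in zip(u, v)) == 1:
                    todo.discard(v)
                    stack.append(v)
        comps.append(frozenset(comp))
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def code_partition(chain: CodonChain, split_disconnected: bool = True) -> Partition:
    """Partition of the chain's codons by encoded amino acid.

    With ``split_disconnected`` each amino-acid group is further split into
    its single-point-mutation connected components (21 blocks for the
    standard code over all 61 sense codons; only serine splits).
    """
    by_aa = defaultdict(list)
    for codon in chain.matrix.labels:
        by_aa[chain.code.translate(codon)].append(codon)
    blocks = []
    for aa in sorted(by_aa):
        if split_disconnected:
            blocks.extend(hamming_components(by_aa[aa]))
        else:
            blocks.append(frozenset(by_aa[aa]))
    return Partition(tuple(blocks))


def aa_block_labels(chain: CodonChain, partition: Partition) -> dict:
    """Map each block's canonical name to an amino-acid display label.

    Amino acids whose codons split into several components get numbered
    labels in component order (largest first): serine becomes S_1 for
    {TCT, TCC, TCA, TCG} and S_2 for {AGT, AGC}.
    """
    by_aa = defaultdict(list)
    for block in partition.blocks:
        aa = chain.code.translate(min(block))
        by_aa[aa].append(block)
    names = {}
    for aa, blocks in by_aa.items():
        blocks.sort(key=lambda b: (-len(b), min(b)))
        for i, b in enumerate(blocks, start=1):
            names[min(b)] = aa if len(blocks) == 1 else f"{aa}_{i}"
    return names


def amino_acid_chain(
    chain: CodonChain,
    exclude=(),
) -> TransitionMatrix:
    """Lump the codon chain to the amino-acid level and optionally drop
    residues.

    The codon chain is lumped by the code partition (serine split into S_1
    and S_2), relabeled to amino-acid letters, then restricted away from the
    residues in ``exclude`` with row renormalization.
    """
    part = code_partition(chain, split_disconnected=True)
    pi = stationary_distribution(chain.matrix)
    macro = lump(chain.matrix, pi, part)
    names = aa_block_labels(chain, part)
    macro = TransitionMatrix(tuple(names[l] for l in macro.labels), macro.P)
    exclude = set(exclude)
    if exclude:
        keep = set(macro.labels) - exclude
        unknown = exclude - set(macro.labels)
        if unknown:
            raise UnknownCodonLabel(f"cannot exclude unknown residues {sorted(unknown)}")
        macro = restrict(macro, keep)
    return macro


@dataclass(frozen=True)
class CodonReport:
    """Everything ``analyze`` computes on a codon chain."""

    gap_index: int
    code_partition: Partition
    code_partition_mi: float
    spectral_partition: Partition | None
    aa_labels: tuple[str, ...]
    aa_trace: MergeTrace
    aa_most_significant: Partition
    newick: str


def analyze(
    chain: CodonChain,
    outdir=None,
    tau: float = TAU_EMPIRICAL,
    epsilon: float | None = None,
    exclude=("W",),
) -> CodonReport:
    """Run the full codon pipeline.

    Steps: eigenvalue spectrum and gap index of the codon matrix; clustering
    of the leading gap-index eigenvectors (checked against the code
    partition); <I> of the code partition; lumping to the amino-acid level;
    exclusion of low-mutability residues (tryptophan by default);
    agglomeration of the amino-acid chain; most-significant aggregation and
    Newick dendrogram.  When ``outdir`` is given, results are written there
    as TSV/JSON/Newick files.
    """
    T = chain.matrix
    spec = spectrum(T)
    gap = detect_gap(spec)
    part = code_partition(chain)
    pi = stationary_distribution(T)
    report_code = is_lumpable(T, part, tau=tau, pi=pi)

    spectral_part = None
    try:
        spectral_part = cluster_elements(spec, range(1, gap + 1), epsilon=epsilon)
    except Exception as e:  # NoValidClustering or degenerate-group expansion
        logger.info("leading %d eigenvectors do not define an aggregation: %s", gap, e)

    aa = amino_acid_chain(chain, exclude=exclude)
    trace = agglomerate(aa)
    best = most_significant(trace)
    nwk = to_newick(trace)

    report = CodonReport(
        gap_index=gap,
        code_partition=part,
        code_partition_mi=report_code.expected_mi,
        spectral_partition=spectral_part,
        aa_labels=aa.labels,
        aa_trace=trace,
        aa_most_significant=best,
        newick=nwk,
    )
    if outdir is not None:
        _write_report(outdir, chain, spec, report)
    return report


def _write_report(outdir, chain: CodonChain, spec, report: CodonReport) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "spectrum.tsv", "w") as fh:
        fh.write("index\treal\timag\tmagnitude\n")
        for i, lam in enumerate(spec.eigenvalues, start=1):
            fh.write(f"{i}\t{lam.real:.12g}\t{lam.imag:.12g}\t{abs(lam):.12g}\n")
    (out / "code_partition.json").write_text(report.code_partition.to_json())
    if report.spectral_partition is not None:
        (out / "spectral_partition.json").write_text(report.spectral_partition.to_json())
    (out / "aa_most_significant.json").write_text(report.aa_most_significant.to_json())
    (out / "dendrogram.nwk").write_text(report.newick + "\n")
    with open(out / "aa_trace.tsv", "w") as fh:
        fh.write("step\tmerged\tn_blocks\texpected_mi_bits\n")
        for t, step in enumerate(report.aa_trace.steps, start=1):
            fh.write(
                f"{t}\t{step.merged_pair[0]}+{step.merged_pair[1]}\t"
                f"{step.partition.n_blocks}\t{step.expected_mi:.12g}\n"
            )
    summary = {
        "n_states": chain.matrix.n_states,
        "gap_index": report.gap_index,
        "code_partition_blocks": report.code_partition.n_blocks,
        "code_partition_mi_bits": report.code_partition_mi,
        "spectral_matches_code": (
            report.spectral_partition == report.code_partition
            if report.spectral_partition is not None
            else None
        ),
        "aa_most_significant_blocks": [
            sorted(b) for b in report.aa_most_significant.blocks
        ],
    }
    (out / "report.json").write_text(json.dumps(summary, indent=1))
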