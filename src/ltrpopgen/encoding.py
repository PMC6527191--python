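"""Multilocus genotype encoding of RT amino-acid alignments.

Each variable alignment column is one locus; residue states (20 amino acids
plus the stop codon) are alleles coded 1..21, gaps are missing data (-9).
Every element is written as a homozygous diploid (two identical rows), the
conventional coding for effectively haploid markers in STRUCTURE-style
input files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import AlignedLineage, InputError

MISSING = -9

#: fixed bijection residue symbol -> allele code (alphabetical; '*' = 21)
ALLELE_CODES: dict[str, int] = {
    aa: i + 1 for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")
}
ALLELE_CODES["*"] = 21

#: inverse mapping code -> symbol
CODE_SYMBOLS: dict[int, str] = {v: k for k, v in ALLELE_CODES.items()}

N_ALLELE_STATES = 21


class NoPolymorphismError(InputError):
    """Raised when an alignment has no variable columns to encode."""


@dataclass
class GenotypeMatrix:
    """Individuals x variable-loci integer allele codes.

    ``codes[i, j]`` is the allele (1..21) of element ``i`` at retained
    alignment column ``locus_columns[j]`` (1-based provenance), or -9 when
    the element has a gap there.
    """

    element_ids: list[str]
    locus_columns: list[int]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.shape != (len(self.element_ids), len(self.locus_columns)):
            raise InputError("codes shape inconsistent with ids/loci")
        valid = (self.codes == MISSING) | (
            (self.codes >= 1) & (self.codes <= N_ALLELE_STATES)
        )
        if not valid.all():
            raise InputError("allele codes must be in 1..21 or -9")
        cols = self.locus_columns
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise InputError("locus_columns must be strictly increasing")

    @property
    def n_elements(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]


def encode_alignment(aln: AlignedLineage) -> GenotypeMatrix:
    """Encode an alignment as a genotype matrix of variable loci.

    A column is *variable* when its non-missing states take >= 2 distinct
    values; columns that vary only through gaps are dropped.  Raises
    :class:`NoPolymorphismError` when nothing is variable (clustering would
    be impossible).
    """
    n, L = aln.n_elements, aln.n_columns
    codes = np.empty((n, L), dtype=np.int64)
    for i, row in enumerate(aln.rows):
        codes[i] = [MISSING if c == "-" else ALLELE_CODES[c] for c in row]

    keep: list[int] = []
    for j in range(L):
        col = codes[:, j]
        states = np.unique(col[col != MISSING])
        if len(states) >= 2:
            keep.append(j)
    if not keep:
        raise NoPolymorphismError(
            f"no polymorphism: alignment {aln.lineage_name!r} has no "
            "variable columns"
        )
    return GenotypeMatrix(
        element_ids=list(aln.element_ids),
        locus_columns=[j + 1 for j in keep],
        codes=codes[:, keep],
    )


def decode_matrix(gm: GenotypeMatrix, lineage_name: str = "decoded") -> AlignedLineage:
    """Rebuild a (loci-only) alignment from a genotype matrix."""
    rows = [
        "".join("-" if c == MISSING else CODE_SYMBOLS[int(c)] for c in row)
        for row in gm.codes
    ]
    return AlignedLineage(lineage_name, list(gm.element_ids), rows)


def write_structure_file(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the classic whitespace-delimited genotype input file.

    Two identical rows per element (homozygous diploid coding); the first
    field is the element label, then one integer allele code per locus.
    Readable by the original STRUCTURE program with MISSING=-9, PLOIDY=2,
    LABEL=1.
    """
    if gm.n_loci == 0:
        raise InputError("refusing to write a 0-locus genotype matrix")
    with open(path, "w") as fh:
        for eid, row in zip(gm.element_ids, gm.codes):
            line = eid + " " + " ".join(str(int(c)) for c in row)
            fh.write(line + "\n")
            fh.write(line + "\n")


def read_structure_file(path: str | Path) -> GenotypeMatrix:
    """Read a homozygous-diploid genotype file back into a matrix.

    The data this format carries here are strictly homozygous, so the two
    rows of each individual must be identical; heterozygous records are
    rejected.  Locus provenance is not stored in the file, so columns are
    renumbered 1..L on read.
    """
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or len(lines) % 2 != 0:
        raise InputError("expected an even, nonzero number of genotype rows")
    ids: list[str] = []
    rows: list[list[int]] = []
    for a, b in zip(lines[::2], lines[1::2]):
        if a != b:
            raise InputError(f"heterozygous record for individual {a[0]!r}")
        ids.append(a[0])
        try:
            rows.append([int(tok) for tok in a[1:]])
        except ValueError as exc:
            raise InputError(f"non-integer genotype token in record {a[0]!r}") from exc
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise InputError("records differ in locus count")
    codes = np.array(rows, dtype=np.int64)
    return GenotypeMatrix(
        element_ids=ids,
        locus_columns=list(range(1, codes.shape[1] + 1)),
        codes=codes,
    )


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Human-readable TSV mirror: header = original alignment columns."""
    with open(path, "w") as fh:
        fh.write("element_id\t" + "\t".join(f"col{c}" for c in gm.locus_columns) + "\n")
        for eid, row in zip(gm.element_ids, gm.codes):
            fh.write(eid + "\t" + "\t".join(str(int(c)) for c in row) + "\n")


def compact_allele_coding(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Recode alleles per locus to dense 0..J_l-1 indices for the sampler.

    Returns ``(X, J, code_maps)`` where ``X[i, l]`` is the dense allele index
    (-1 for missing), ``J[l]`` the number of distinct observed alleles at
    locus ``l``, and ``code_maps[l]`` the original 1..21 code for each dense
    index.  The model's allele space at each locus is exactly the observed
    allele set, as in the classic clustering program.
    """
    n, L = gm.codes.shape
    X = np.full((n, L), -1, dtype=np.int8)
    J = np.empty(L, dtype=np.int64)
    code_maps: list[np.ndarray] = []
    for l in range(L):
        col = gm.codes[:, l]
        obs = np.unique(col[col != MISSING])
        code_maps.append(obs)
        J[l] = len(obs)
        lookup = {int(c): j for j, c in enumerate(obs)}
        for i in range(n):
            if col[i] != MISSING:
                X[i, l] = lookup[int(col[i])]
    return X, J, code_maps
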