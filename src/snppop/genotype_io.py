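"""PLINK text genotype I/O and the core genotype/haplotype containers.

The central object is :class:`GenotypeMatrix`: diploid biallelic genotypes
coded as counts of ``alleleB`` (0/1/2, missing = -1) over an ordered marker
map.  ``alleleB`` is always the lexicographically larger of the two alleles
observed at a marker, so the orientation of signed LD statistics is a pure
function of the data and is shared across populations genotyped on the same
array — a requirement for comparing gametic phase between populations.

Conventions
-----------
* coordinates are 1-based; intervals include both endpoint SNP positions;
* chromosome labels: 1-26 = ovine autosomes, 27 = X, 0 = unknown placement;
* half-missing PED genotypes (one allele ``0``) are set fully missing;
* a marker with fewer than two observed alleles gets placeholder allele
  labels (``alleleB='0'``, and ``alleleA='N'`` if nothing was observed) —
  genotype codes still round-trip exactly through PED/MAP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "MISSING",
    "N_AUTOSOMES",
    "X_CHROMOSOME",
    "UNKNOWN_CHROMOSOME",
    "GenotypeParseError",
    "MarkerRecord",
    "GenotypeMatrix",
    "HaplotypeMatrix",
    "read_ped_map",
    "write_ped_map",
    "read_phased",
    "write_phased",
    "subset",
]

MISSING: int = -1
N_AUTOSOMES: int = 26
X_CHROMOSOME: int = 27
UNKNOWN_CHROMOSOME: int = 0

_VALID_CODES = frozenset({-1, 0, 1, 2})


class GenotypeParseError(ValueError):
    """Raised when a PED/MAP/haplotype file is malformed or inconsistent."""


def _parse_chromosome(token: str) -> int:
    try:
        return int(token)
    except ValueError:
        label = token.upper()
        if label == "X":
            return X_CHROMOSOME
        return UNKNOWN_CHROMOSOME


@dataclass(frozen=True)
class MarkerRecord:
    """One SNP on the marker map."""

    id: str
    chromosome: int
    position_bp: int
    alleleA: str
    alleleB: str
    position_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"marker {self.id}: position_bp must be >= 1")
        if self.alleleA == self.alleleB:
            raise ValueError(f"marker {self.id}: alleleA == alleleB ({self.alleleA!r})")

    @property
    def is_autosomal(self) -> bool:
        return 1 <= self.chromosome <= N_AUTOSOMES


@dataclass
class GenotypeMatrix:
    """samples x markers diploid genotypes, coded as copies of ``alleleB``."""

    sample_ids: list[str]
    populations: list[str]
    markers: list[MarkerRecord]
    calls: np.ndarray  # int8, shape (n_samples, n_markers); MISSING = -1

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, m = len(self.sample_ids), len(self.markers)
        if len(self.populations) != n:
            raise ValueError("populations/sample_ids length mismatch")
        if self.calls.shape != (n, m):
            raise ValueError(f"calls shape {self.calls.shape} != ({n}, {m})")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if m and not set(np.unique(self.calls)).issubset(_VALID_CODES):
            raise ValueError("calls contain codes outside {-1, 0, 1, 2}")
        # positions strictly increasing within each placed chromosome
        chroms = self.chromosomes
        pos = self.positions
        for c in np.unique(chroms):
            if c == UNKNOWN_CHROMOSOME:
                continue  # unplaced markers carry no meaningful order
            p = pos[chroms == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"chromosome {c}: positions not strictly increasing")

    # -- derived views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def samples(self) -> list[tuple[str, str]]:
        return list(zip(self.sample_ids, self.populations))

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([m.chromosome for m in self.markers], dtype=np.int64)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position_bp for m in self.markers], dtype=np.int64)

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def chromosome_groups(self) -> Iterator[tuple[int, np.ndarray]]:
        """Yield (chromosome, marker index array) in order of first appearance."""
        chroms = self.chromosomes
        seen: list[int] = []
        for c in chroms:
            if c not in seen:
                seen.append(int(c))
        for c in seen:
            yield c, np.flatnonzero(chroms == c)

    def subset(self, sample_mask=None, marker_mask=None) -> "GenotypeMatrix":
        return subset(self, sample_mask, marker_mask)


@dataclass
class HaplotypeMatrix:
    """2n haplotype rows (consecutive pairs = one sample) x markers, alleles in {0,1}."""

    sample_ids: list[str]
    populations: list[str]
    markers: list[MarkerRecord]
    haplotypes: np.ndarray  # uint8, shape (2*n_samples, n_markers)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        n, m = len(self.sample_ids), len(self.markers)
        if self.haplotypes.shape != (2 * n, m):
            raise ValueError(
                f"haplotypes shape {self.haplotypes.shape} != ({2 * n}, {m})"
            )
        if m and n and self.haplotypes.max(initial=0) > 1:
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position_bp for m in self.markers], dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([m.chromosome for m in self.markers], dtype=np.int64)

    def chromosome_groups(self) -> Iterator[tuple[int, np.ndarray]]:
        yield from GenotypeMatrix.chromosome_groups(self)  # type: ignore[arg-type]

    def to_genotypes(self) -> GenotypeMatrix:
        calls = (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            populations=list(self.populations),
            markers=list(self.markers),
            calls=calls,
        )

    def check_consistency(self, g: GenotypeMatrix) -> None:
        """Verify that haplotype pairs sum to the genotype codes at non-missing sites."""
        if g.n_samples != self.n_samples or g.n_markers != self.n_markers:
            raise GenotypeParseError("haplotype/genotype dimension mismatch")
        sums = self.haplotypes[0::2].astype(np.int8) + self.haplotypes[1::2]
        bad = (sums != g.calls) & (g.calls != MISSING)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise GenotypeParseError(
                "haplotypes inconsistent with genotypes at "
                f"(sample {g.sample_ids[i]!r}, marker {g.markers[j].id!r})"
            )

    def subset(self, sample_mask=None, marker_mask=None) -> "HaplotypeMatrix":
        smask = _as_index(sample_mask, self.n_samples)
        mmask = _as_index(marker_mask, self.n_markers)
        rows = np.stack([2 * smask, 2 * smask + 1], axis=1).ravel()
        return HaplotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in smask],
            populations=[self.populations[i] for i in smask],
            markers=[self.markers[j] for j in mmask],
            haplotypes=self.haplotypes[np.ix_(rows, mmask)],
        )


def _as_index(mask, n: int) -> np.ndarray:
    if mask is None:
        return np.arange(n)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape != (n,):
            raise ValueError(f"mask length {mask.shape} != {n}")
        return np.flatnonzero(mask)
    return mask.astype(np.intp)


def subset(g: GenotypeMatrix, sample_mask=None, marker_mask=None) -> GenotypeMatrix:
    """Order-preserving selection of samples and/or markers (boolean or index masks)."""
    smask = _as_index(sample_mask, g.n_samples)
    mmask = _as_index(marker_mask, g.n_markers)
    return GenotypeMatrix(
        sample_ids=[g.sample_ids[i] for i in smask],
        populations=[g.populations[i] for i in smask],
        markers=[g.markers[j] for j in mmask],
        calls=g.calls[np.ix_(smask, mmask)],
    )


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def _read_map(map_path) -> list[tuple[str, int, float, int]]:
    rows = []
    ids = set()
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) != 4:
                raise GenotypeParseError(
                    f"{map_path}:{lineno}: expected 4 MAP columns, got {len(tokens)}"
                )
            chrom = _parse_chromosome(tokens[0])
            snp_id = tokens[1]
            if snp_id in ids:
                raise GenotypeParseError(f"{map_path}:{lineno}: duplicate marker id {snp_id!r}")
            ids.add(snp_id)
            rows.append((snp_id, chrom, float(tokens[2]), int(tokens[3])))
    return rows


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeMatrix`.

    Genotype codes count copies of ``alleleB``, the lexicographically second
    of the two alleles observed at the marker.  Half-missing genotype calls
    (one allele ``0``) become fully missing.
    """
    map_rows = _read_map(map_path)
    m = len(map_rows)

    sample_ids: list[str] = []
    populations: list[str] = []
    call_rows: list[np.ndarray] = []
    # provisional orientation: first observed allele at each marker
    allele1 = np.full(m, "", dtype="U8")
    allele2 = np.full(m, "", dtype="U8")

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) != 6 + 2 * m:
                raise GenotypeParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns "
                    f"({m} markers in {map_path}), got {len(tokens)}"
                )
            populations.append(tokens[0])
            sample_ids.append(tokens[1])
            a1 = np.array(tokens[6::2], dtype="U8")
            a2 = np.array(tokens[7::2], dtype="U8")
            for a in (a1, a2):
                present = a != "0"
                new1 = present & (allele1 == "")
                allele1[new1] = a[new1]
                new2 = present & (allele1 != "") & (a != allele1) & (allele2 == "")
                allele2[new2] = a[new2]
                bad = present & (a != allele1) & (a != allele2)
                if np.any(bad):
                    j = int(np.flatnonzero(bad)[0])
                    raise GenotypeParseError(
                        f"{ped_path}:{lineno}: marker {map_rows[j][0]!r} has more "
                        f"than two alleles (saw {a[j]!r})"
                    )
            miss = (a1 == "0") | (a2 == "0")
            # count copies differing from the provisional first allele
            code = (a1 != allele1).astype(np.int8) + (a2 != allele1)
            code[miss] = MISSING
            call_rows.append(code)

    calls = (
        np.array(call_rows, dtype=np.int8)
        if call_rows
        else np.empty((0, m), dtype=np.int8)
    )
    # fix orientation: alleleA = lexicographically smaller observed allele
    flip = (allele2 != "") & (allele1 > allele2)
    if calls.size:
        fcols = calls[:, flip]
        fcols[fcols != MISSING] = 2 - fcols[fcols != MISSING]
        calls[:, flip] = fcols
    a_final = np.where(flip, allele2, allele1)
    b_final = np.where(flip, allele1, allele2)
    a_final[a_final == ""] = "N"  # marker with no observed allele
    b_final[b_final == ""] = "0"  # marker with <2 observed alleles

    markers = [
        MarkerRecord(snp_id, chrom, bp, str(a), str(b), cm)
        for (snp_id, chrom, cm, bp), a, b in zip(map_rows, a_final, b_final)
    ]
    return GenotypeMatrix(sample_ids, populations, markers, calls)


_PAIRS = {0: "{a} {a}", 1: "{a} {b}", 2: "{b} {b}", MISSING: "0 0"}


def write_ped_map(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK text PED/MAP such that :func:`read_ped_map` reproduces ``g``."""
    with open(map_path, "w") as fh:
        for mk in g.markers:
            fh.write(f"{mk.chromosome}\t{mk.id}\t{mk.position_cm:g}\t{mk.position_bp}\n")
    lookup = [
        [tmpl.format(a=mk.alleleA, b=mk.alleleB) for code, tmpl in sorted(_PAIRS.items())]
        for mk in g.markers
    ]
    with open(ped_path, "w") as fh:
        for i, (sid, pop) in enumerate(g.samples):
            fields = [pop, sid, "0", "0", "0", "-9"]
            row = g.calls[i]
            fields.extend(lookup[j][code + 1] for j, code in enumerate(row))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# phased haplotype table
# ---------------------------------------------------------------------------

def read_phased(haps_path, g: GenotypeMatrix) -> HaplotypeMatrix:
    """Read a whitespace haplotype table (one row per haplotype, 0/1 alleles).

    Rows come in consecutive pairs per sample, aligned to ``g``'s sample and
    marker order; consistency with the genotypes is enforced.
    """
    rows: list[np.ndarray] = []
    with open(haps_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) != g.n_markers:
                raise GenotypeParseError(
                    f"{haps_path}:{lineno}: expected {g.n_markers} alleles, got {len(tokens)}"
                )
            row = np.array(tokens, dtype=np.uint8)
            if row.size and row.max() > 1:
                raise GenotypeParseError(f"{haps_path}:{lineno}: alleles must be 0/1")
            rows.append(row)
    if len(rows) != 2 * g.n_samples:
        raise GenotypeParseError(
            f"{haps_path}: expected {2 * g.n_samples} haplotype rows, got {len(rows)}"
        )
    haps = (
        np.array(rows, dtype=np.uint8)
        if rows
        else np.empty((0, g.n_markers), dtype=np.uint8)
    )
    h = HaplotypeMatrix(list(g.sample_ids), list(g.populations), list(g.markers), haps)
    h.check_consistency(g)
    return h


def write_phased(h: HaplotypeMatrix, haps_path) -> None:
    with open(haps_path, "w") as fh:
        for row in h.haplotypes:
            fh.write(" ".join(map(str, row)) + "\n")
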