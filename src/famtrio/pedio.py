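"""Readers and writers: PED/MAP pedigrees, the compact genotype format, results.

Two on-disk representations are supported:

* standard whitespace-delimited PED/MAP (one line per individual, two allele
  columns per marker, '0' for a missing allele), and
* a transposed compact text matrix: a header of the six PED columns (one
  ``#``-prefixed line per individual) followed by one line per marker —
  marker id, chromosome, position, ref allele, alt allele, and one character
  per individual ('0'/'1'/'2' alternate-allele dosage, '.' missing).  One
  character per genotype versus at least four in PED ("A A " and the
  separator) puts the compact file at well under half the PED size for the
  same data, which matters at whole-genome scale.

Both load into a :class:`FamilyData` holding a samples table, a markers
table and an int8 dosage matrix, from which nuclear families are decomposed
into father-mother-offspring trios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fbat import EPS
from .genetics import MISSING, Sex, Trio

__all__ = [
    "FamilyData",
    "read_ped",
    "write_ped",
    "read_compact",
    "write_compact",
    "write_results",
    "format_pvalue",
]

SAMPLE_COLS = ["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"]
MARKER_COLS = ["marker_id", "chrom", "pos", "ref", "alt"]


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


@dataclass
class FamilyData:
    """Pedigree samples, marker metadata and an alt-allele dosage matrix.

    ``samples`` has the six PED columns (sex 1=male/2=female/0=unknown;
    phenotype 2=affected, 1=unaffected, 0 or -9 = unknown).  ``genotypes``
    is (n_samples, n_markers) int8 with -1 for missing.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        dup = self.samples.duplicated(subset=["family_id", "individual_id"])
        if dup.any():
            raise ParseError(f"duplicated individual ids: rows {list(np.flatnonzero(dup))}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def trio_index(self) -> pd.DataFrame:
        """One row per father-mother-offspring trio.

        Offspring are individuals naming at least one parent; a named parent
        without a record (or named '0') contributes missing genotypes.
        Offspring with unknown phenotype are excluded (and counted in the
        frame's ``n_excluded_phenotype`` attr).  Row indices into
        ``genotypes`` are -1 for absent members.
        """
        s = self.samples
        key = pd.MultiIndex.from_frame(s[["family_id", "individual_id"]])
        lookup = pd.Series(np.arange(len(s)), index=key)

        rows = []
        n_excluded = 0
        for i, rec in enumerate(s.itertuples(index=False)):
            if rec.father_id == "0" and rec.mother_id == "0":
                continue  # founder
            pheno = int(rec.phenotype)
            if pheno not in (1, 2):
                n_excluded += 1
                continue
            fa = lookup.get((rec.family_id, rec.father_id), -1) if rec.father_id != "0" else -1
            mo = lookup.get((rec.family_id, rec.mother_id), -1) if rec.mother_id != "0" else -1
            rows.append(
                {
                    "family_id": rec.family_id,
                    "offspring_id": rec.individual_id,
                    "father_row": int(fa),
                    "mother_row": int(mo),
                    "offspring_row": i,
                    "sex": int(rec.sex) if int(rec.sex) in (1, 2) else 2,
                    "affected": pheno == 2,
                }
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "family_id",
                "offspring_id",
                "father_row",
                "mother_row",
                "offspring_row",
                "sex",
                "affected",
            ],
        )
        df.attrs["n_excluded_phenotype"] = n_excluded
        return df

    def trios_for_marker(self, j: int, trio_index: pd.DataFrame | None = None) -> list[Trio]:
        """Trio objects at marker ``j`` (X-male dosages collapse 2 -> 1)."""
        idx = self.trio_index() if trio_index is None else trio_index
        g = self.genotypes[:, j]
        is_x = str(self.markers.iloc[j]["chrom"]).upper() in ("X", "23")
        out = []
        for rec in idx.itertuples(index=False):
            fa = int(g[rec.father_row]) if rec.father_row >= 0 else MISSING
            mo = int(g[rec.mother_row]) if rec.mother_row >= 0 else MISSING
            of = int(g[rec.offspring_row])
            if is_x:
                if fa == 2:
                    fa = 1
                if rec.sex == 1 and of == 2:
                    of = 1
            out.append(
                Trio(
                    father=fa,
                    mother=mo,
                    offspring=of,
                    affected=bool(rec.affected),
                    sex=Sex(rec.sex),
                    family_id=str(rec.family_id),
                )
            )
        return out


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

def _read_map(map_path) -> pd.DataFrame:
    markers = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (4, 6):
                raise ParseError(
                    f"{map_path}:{ln}: expected 4 (chrom id cM pos) or 6 "
                    f"(... ref alt) columns, got {len(parts)}"
                )
            ref, alt = (parts[4], parts[5]) if len(parts) == 6 else (None, None)
            markers.append(
                {
                    "marker_id": parts[1],
                    "chrom": parts[0],
                    "pos": int(parts[3]),
                    "ref": ref,
                    "alt": alt,
                }
            )
    return pd.DataFrame(markers, columns=MARKER_COLS)


def read_ped(ped_path, map_path) -> FamilyData:
    """Load a PED/MAP pair into dosages against the alt allele.

    When the MAP file declares ref/alt (6-column extension) those orient the
    dosage; otherwise the first allele observed at each marker becomes the
    reference.  More than two alleles at a marker is an error.
    """
    markers = _read_map(map_path)
    n_m = len(markers)
    ref = list(markers["ref"])
    alt = list(markers["alt"])

    samples = []
    geno_rows = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_m:
                raise ParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_m} columns for "
                    f"{n_m} markers, got {len(parts)}"
                )
            samples.append(dict(zip(SAMPLE_COLS, parts[:6])))
            row = np.empty(n_m, dtype=np.int8)
            for j in range(n_m):
                a1, a2 = parts[6 + 2 * j], parts[7 + 2 * j]
                if (a1 == "0") != (a2 == "0"):
                    raise ParseError(
                        f"{ped_path}:{ln}: half-missing allele pair "
                        f"'{a1} {a2}' at marker {markers['marker_id'][j]}"
                    )
                if a1 == "0":
                    row[j] = MISSING
                    continue
                dose = 0
                for a in (a1, a2):
                    if ref[j] is None:
                        ref[j] = a
                    if a == ref[j]:
                        pass
                    elif alt[j] is None:
                        alt[j] = a
                        dose += 1
                    elif a == alt[j]:
                        dose += 1
                    else:
                        raise ParseError(
                            f"{ped_path}:{ln}: third allele {a!r} at "
                            f"bi-allelic marker {markers['marker_id'][j]}"
                        )
                row[j] = dose
            geno_rows.append(row)

    markers["ref"] = [r if r is not None else "A" for r in ref]
    markers["alt"] = [a if a is not None else "B" for a in alt]
    sdf = pd.DataFrame(samples, columns=SAMPLE_COLS)
    sdf["sex"] = sdf["sex"].astype(int)
    sdf["phenotype"] = sdf["phenotype"].astype(int)
    geno = np.vstack(geno_rows) if geno_rows else np.empty((0, n_m), dtype=np.int8)
    return FamilyData(samples=sdf, markers=markers, genotypes=geno)


def write_ped(data: FamilyData, ped_path, map_path) -> None:
    """Write a PED/MAP pair (6-column MAP carrying the ref/alt alleles)."""
    with open(map_path, "w") as fh:
        for rec in data.markers.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.marker_id}\t0\t{rec.pos}\t{rec.ref}\t{rec.alt}\n")
    with open(ped_path, "w") as fh:
        for i, rec in enumerate(data.samples.itertuples(index=False)):
            fields = [
                str(rec.family_id),
                str(rec.individual_id),
                str(rec.father_id),
                str(rec.mother_id),
                str(rec.sex),
                str(rec.phenotype),
            ]
            for j, d in enumerate(data.genotypes[i]):
                ref = data.markers["ref"].iloc[j]
                alt = data.markers["alt"].iloc[j]
                if d == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [alt if d >= 1 else ref, alt if d == 2 else ref]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# compact format
# ---------------------------------------------------------------------------

_MAGIC = "##famtrio-compact v1"
_DOSAGE_CHARS = {0: "0", 1: "1", 2: "2", MISSING: "."}
_CHAR_DOSAGE = {v: k for k, v in _DOSAGE_CHARS.items()}


def write_compact(data: FamilyData, path) -> None:
    """Write the transposed one-character-per-genotype matrix."""
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        for rec in data.samples.itertuples(index=False):
            fh.write(
                f"#{rec.family_id} {rec.individual_id} {rec.father_id} "
                f"{rec.mother_id} {rec.sex} {rec.phenotype}\n"
            )
        geno = data.genotypes
        for j, rec in enumerate(data.markers.itertuples(index=False)):
            chars = "".join(_DOSAGE_CHARS[int(d)] for d in geno[:, j])
            fh.write(f"{rec.marker_id} {rec.chrom} {rec.pos} {rec.ref} {rec.alt} {chars}\n")


def read_compact(path) -> FamilyData:
    """Read the compact format back into a :class:`FamilyData`."""
    samples = []
    marker_rows = []
    geno_cols = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _MAGIC:
            raise ParseError(f"{path}:1: not a compact genotype file (missing magic line)")
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) != 6:
                    raise ParseError(f"{path}:{ln}: sample header needs 6 columns")
                samples.append(dict(zip(SAMPLE_COLS, parts)))
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ParseError(f"{path}:{ln}: marker line needs 6 columns")
            mid, chrom, pos, ref, alt, chars = parts
            if len(chars) != len(samples):
                raise ParseError(
                    f"{path}:{ln}: marker {mid}: {len(chars)} genotype characters "
                    f"for {len(samples)} samples"
                )
            try:
                col = np.array([_CHAR_DOSAGE[c] for c in chars], dtype=np.int8)
            except KeyError as err:
                raise ParseError(f"{path}:{ln}: marker {mid}: bad genotype character {err}")
            marker_rows.append(
                {"marker_id": mid, "chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt}
            )
            geno_cols.append(col)

    sdf = pd.DataFrame(samples, columns=SAMPLE_COLS)
    if len(sdf):
        sdf["sex"] = sdf["sex"].astype(int)
        sdf["phenotype"] = sdf["phenotype"].astype(int)
    mdf = pd.DataFrame(marker_rows, columns=MARKER_COLS)
    geno = (
        np.column_stack(geno_cols)
        if geno_cols
        else np.empty((len(sdf), 0), dtype=np.int8)
    )
    return FamilyData(samples=sdf, markers=mdf, genotypes=geno)


def detect_format(path) -> str:
    """'compact' for the transposed matrix, 'ped' otherwise (by content)."""
    with open(path) as fh:
        return "compact" if fh.readline().rstrip("\n") == _MAGIC else "ped"


def from_simulation(ped) -> FamilyData:
    """Pack a simulated :class:`~famtrio.simulation.PedigreeSet` for writing.

    Fathers get individual id '1', mothers '2', offspring '3', '4', ...
    within each family; markers are named M000001... on chromosome 1 with
    1-based positions and A/B ref/alt alleles.
    """
    n_fam = ped.config.n_families
    n_m = ped.config.n_markers
    affected = ped.affected

    rows = []
    geno = []
    for fam in range(n_fam):
        fid = f"F{fam:05d}"
        rows.append([fid, "1", "0", "0", 1, 1])
        geno.append(ped.father_geno[fam])
        rows.append([fid, "2", "0", "0", 2, 1])
        geno.append(ped.mother_geno[fam])
    child_no = np.full(n_fam, 3)
    for off in range(ped.n_offspring):
        fam = int(ped.off_family[off])
        fid = f"F{fam:05d}"
        pheno = 0 if affected is None else (2 if affected[off] else 1)
        rows.append([fid, str(child_no[fam]), "1", "2", int(ped.off_sex[off]), pheno])
        child_no[fam] += 1
        geno.append(ped.off_geno[off])

    samples = pd.DataFrame(rows, columns=SAMPLE_COLS)
    markers = pd.DataFrame(
        {
            "marker_id": [f"M{j + 1:06d}" for j in range(n_m)],
            "chrom": "1",
            "pos": np.arange(1, n_m + 1),
            "ref": "A",
            "alt": "B",
        }
    )
    return FamilyData(samples=samples, markers=markers, genotypes=np.vstack(geno))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def format_pvalue(p: float) -> str:
    """P-values below machine epsilon print as '<2.22e-16'; NaN as 'NA'."""
    if p != p:  # NaN
        return "NA"
    if p < EPS:
        return f"<{EPS:.3g}"
    return f"{p:.6g}"


def write_results(df: pd.DataFrame, path_or_buf) -> None:
    """Tab-separated results with a header; p-value columns get the epsilon floor."""
    out = df.copy()
    for col in out.columns:
        if col.startswith("p") and out[col].dtype.kind == "f":
            out[col] = out[col].map(format_pvalue)
    out.to_csv(path_or_buf, sep="\t", index=False, float_format="%.6g", na_rep="NA")
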