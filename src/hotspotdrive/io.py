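"""File formats and validated in-memory structures.

Coordinates are 0-based half-open everywhere inside the package; 1-based
conventions appear only at I/O boundaries (VCF positions).  Recombination
maps follow the HapMap convention: each row's rate (cM/Mb) is valid from
the stated position up to the next row's position, and the map provides no
information outside [first, last] position.  Every table the package writes
starts with a provenance header (# hotspotdrive <version> seed=... ).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "encode_seq",
    "decode_seq",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "RecombMap",
    "read_recomb_map",
    "write_recomb_map",
    "read_af_table",
    "provenance_header",
    "write_table",
    "MalformedInputError",
]

PACKAGE_VERSION = "0.1.0"

BASES = "ACGT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
MISSING = np.uint8(255)


class MalformedInputError(ValueError):
    """Raised for malformed input files; carries per-line error messages."""

    def __init__(self, path, errors: list[str]):
        self.errors = errors
        head = "; ".join(errors[:5])
        more = f" (+{len(errors) - 5} more)" if len(errors) > 5 else ""
        super().__init__(f"{path}: {head}{more}")


def encode_seq(seq: str) -> np.ndarray:
    """ACGT -> 0..3 uint8; anything else (N, gaps) -> 255 (missing)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT" + b"N" * 252, dtype=np.uint8)
    return lut[np.minimum(codes, 4)].tobytes().decode("ascii")


def provenance_header(seed=None, extra: dict | None = None) -> str:
    parts = [f"# hotspotdrive {PACKAGE_VERSION}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    for k, v in (extra or {}).items():
        parts.append(f"{k}={v}")
    return " ".join(parts)


def config_hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {name: sequence}; alphabet restricted to ACGTN-."""
    records = {}
    allowed = set("ACGTN-")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - allowed
        if bad:
            raise MalformedInputError(
                path, [f"record {rec.id}: invalid characters {sorted(bad)}"]
            )
        records[rec.id] = seq
    return records


def write_fasta(records: dict[str, str], path, seed=None) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description=provenance_header(seed).lstrip("# "))
        for name, seq in records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 (0-based half-open) with per-line validation."""
    rows, errors = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                errors.append(f"line {lineno}: fewer than 3 columns")
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinates")
                continue
            if start < 0 or end <= start:
                errors.append(f"line {lineno}: requires 0 <= start < end")
                continue
            row = [fields[0], start, end]
            row.append(fields[3] if len(fields) > 3 else ".")
            row.append(fields[4] if len(fields) > 4 else ".")
            row.append(fields[5] if len(fields) > 5 else ".")
            rows.append(row)
    if errors:
        raise MalformedInputError(path, errors)
    return pd.DataFrame(rows, columns=_BED_COLUMNS)


def write_bed(df: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        cols = [c for c in _BED_COLUMNS if c in df.columns]
        df[cols].to_csv(fh, sep="\t", header=False, index=False)


def intervals_overlap(start: int, end: int, track: pd.DataFrame, chrom: str) -> bool:
    """Any-overlap rule: [start, end) shares >= 1 bp with a track interval."""
    sub = track[track["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def overlap_mask(starts: np.ndarray, ends: np.ndarray, track: pd.DataFrame,
                 chrom: str) -> np.ndarray:
    """Vectorized any-overlap of many query intervals against a track."""
    sub = track[track["chrom"] == chrom]
    if len(sub) == 0:
        return np.zeros(len(starts), dtype=bool)
    ts = sub["start"].to_numpy()
    te = sub["end"].to_numpy()
    order = np.argsort(ts)
    ts, te = ts[order], te[order]
    # running max of interval ends, for intervals starting before each query end
    te_max = np.maximum.accumulate(te)
    idx = np.searchsorted(ts, ends, side="left") - 1
    out = np.zeros(len(starts), dtype=bool)
    ok = idx >= 0
    out[ok] = te_max[idx[ok]] > starts[ok]
    return out


# ---------------------------------------------------------------------------
# Recombination map (HapMap convention)
# ---------------------------------------------------------------------------


@dataclass
class RecombMap:
    """Piecewise-constant crossover-rate map.

    ``positions`` (bp, ascending) and ``rates`` (cM/Mb): rates[i] applies on
    [positions[i], positions[i+1]); the final rate is unused (conventionally
    0).  ``cum_cm`` is the genetic map in cM, anchored at 0 at the first
    position.  Queries outside the covered span return NaN.
    """

    chrom_maps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @classmethod
    def from_arrays(cls, chrom: str, positions, rates) -> "RecombMap":
        positions = np.asarray(positions, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if np.any(np.diff(positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")
        cum = np.concatenate(
            [[0.0], np.cumsum(rates[:-1] * np.diff(positions) / 1e6)]
        )
        return cls({chrom: (positions, rates, cum)})

    def genetic_position(self, chrom: str, pos) -> np.ndarray:
        """Cumulative cM at physical position(s); NaN outside coverage."""
        positions, _, cum = self.chrom_maps[chrom]
        pos = np.asarray(pos, dtype=float)
        out = np.interp(pos, positions, cum)
        out = np.where((pos < positions[0]) | (pos > positions[-1]), np.nan, out)
        return out

    def mean_rate(self, chrom: str, start: float, end: float) -> float:
        """bp-weighted mean rate (cM/Mb) over [start, end); NaN if the
        window is not fully covered."""
        if end <= start:
            raise ValueError("end must exceed start")
        if chrom not in self.chrom_maps:
            return np.nan
        cm = self.genetic_position(chrom, np.array([start, end]))
        if np.any(np.isnan(cm)):
            return np.nan
        return float((cm[1] - cm[0]) / ((end - start) / 1e6))

    def span(self, chrom: str) -> tuple[float, float]:
        positions, _, _ = self.chrom_maps[chrom]
        return float(positions[0]), float(positions[-1])


def read_recomb_map(path) -> RecombMap:
    """Read a HapMap-style map TSV: Chromosome, Position(bp), Rate(cM/Mb),
    Map(cM).  Positions must be sorted per chromosome."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    cols = {c.lower().split("(")[0]: c for c in df.columns}
    try:
        chrom_c = cols["chromosome"]
        pos_c = cols["position"]
        rate_c = cols["rate"]
    except KeyError as exc:
        raise MalformedInputError(path, [f"missing column {exc}"]) from exc
    out = RecombMap()
    for chrom, sub in df.groupby(chrom_c, sort=False):
        pos = sub[pos_c].to_numpy(dtype=float)
        if np.any(np.diff(pos) <= 0):
            bad = int(np.argmax(np.diff(pos) <= 0)) + 2
            raise MalformedInputError(
                path, [f"{chrom}: positions not strictly increasing near row {bad}"]
            )
        single = RecombMap.from_arrays(str(chrom), pos, sub[rate_c].to_numpy(dtype=float))
        out.chrom_maps[str(chrom)] = single.chrom_maps[str(chrom)]
    return out


def write_recomb_map(rmap: RecombMap, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        fh.write("Chromosome\tPosition(bp)\tRate(cM/Mb)\tMap(cM)\n")
        for chrom, (pos, rates, cum) in rmap.chrom_maps.items():
            for p, r, c in zip(pos, rates, cum):
                fh.write(f"{chrom}\t{int(p)}\t{r:.6g}\t{c:.8g}\n")


# ---------------------------------------------------------------------------
# Allele-frequency tables (TSV or minimal VCF)
# ---------------------------------------------------------------------------


def read_af_table(path) -> pd.DataFrame:
    """Allele frequencies as a DataFrame (chrom, pos, ref, alt, af) with
    0-based positions.  Accepts a 5-column TSV (CHROM POS REF ALT AF,
    1-based POS) or a VCF with AF in INFO (parsed with pysam)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        import pysam

        rows = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                af = rec.info.get("AF")
                if af is None:
                    continue
                af = af[0] if isinstance(af, tuple) else af
                rows.append(
                    (rec.chrom, rec.pos - 1, rec.ref, rec.alts[0], float(af))
                )
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"])
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower().lstrip("#") for c in df.columns]
    need = {"chrom", "pos", "ref", "alt", "af"}
    if not need <= set(df.columns):
        raise MalformedInputError(path, [f"missing columns {need - set(df.columns)}"])
    errors = []
    if (df["af"] < 0).any() or (df["af"] > 1).any():
        errors.append("AF outside [0, 1]")
    if errors:
        raise MalformedInputError(path, errors)
    df = df[["chrom", "pos", "ref", "alt", "af"]].copy()
    df["pos"] = df["pos"].astype(int) - 1  # 1-based on disk
    return df


# ---------------------------------------------------------------------------
# Generic provenance-stamped tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path, seed=None, extra: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, extra) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
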