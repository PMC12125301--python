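"""Reading/writing of single-cell VDJ contig tables and per-cell clonotype assembly.

Input tables follow the 10x cellranger-vdj ``filtered_contig_annotations.csv``
layout (one row per assembled contig, one or more rows per cell barcode).
Only productive contigs with a CDR3 sequence participate in clonotype calling;
per barcode and locus, at most two chains are retained, ranked by UMI support.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

#: Loci that participate in clonotype keys. Anything else is "other".
TCR_CHAINS = ("TRA", "TRB")

#: Standard field -> cellranger-vdj column name.
CELLRANGER_DIALECT = {
    "barcode": "barcode",
    "chain": "chain",
    "cdr3_aa": "cdr3",
    "cdr3_nt": "cdr3_nt",
    "v_gene": "v_gene",
    "j_gene": "j_gene",
    "productive": "productive",
    "umis": "umis",
    "reads": "reads",
}

#: Fields that must be resolvable in the header.
MANDATORY_FIELDS = ("barcode", "chain", "cdr3_nt", "productive", "umis")

_TRUTHY = {"true", "t", "1", "yes"}
_FALSY = {"false", "f", "0", "no", "none", ""}


class ContigFormatError(ValueError):
    """The contig table does not conform to the expected column layout."""


@dataclass(frozen=True)
class ContigRecord:
    """One assembled VDJ contig for one cell barcode."""

    barcode: str
    chain: str  # "TRA", "TRB", or "other"
    cdr3_aa: str
    cdr3_nt: str
    v_gene: str
    j_gene: str
    productive: bool
    umis: int
    reads: int

    def __post_init__(self) -> None:
        if self.umis < 0 or self.reads < 0:
            raise ValueError("umis and reads must be non-negative")


@dataclass(frozen=True)
class ChainPolicy:
    """How chains are retained per cell when building clonotype keys.

    max_per_locus
        Cap on productive chains kept per locus (cells occasionally carry two
        rearranged TRA or TRB chains; more than two is treated as noise).
    require_trb
        If True, cells without a productive TRB chain are dropped instead of
        being keyed by TRA alone (beta-only keying convention).
    barcode_suffix
        Regex stripped from the end of barcodes (cellranger GEM-well suffix).
    """

    max_per_locus: int = 2
    require_trb: bool = False
    barcode_suffix: str = r"-\d+$"


@dataclass(frozen=True)
class CellClonotype:
    """One T cell's clonotype call, built from its retained productive chains."""

    barcode: str
    clonotype_key: str
    n_tra: int
    n_trb: int
    #: Representative CDR3beta amino-acid sequence (highest-UMI TRB; TRA
    #: fallback for beta-less cells). Used by sequence-similarity analyses.
    cdr3b_aa: str = ""


def _parse_bool(raw: str) -> bool | None:
    s = raw.strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    return None


def read_contig_table(
    path,
    dialect: dict[str, str] | None = None,
) -> list[ContigRecord]:
    """Read a contig annotation CSV into :class:`ContigRecord` objects.

    Parameters
    ----------
    path
        CSV file in the cellranger-vdj contig-annotation layout.
    dialect
        Optional mapping from standard field names (keys of
        :data:`CELLRANGER_DIALECT`) to the file's actual column names.
        Unmapped fields fall back to the cellranger names; unknown columns in
        the file are ignored.

    Raises
    ------
    ContigFormatError
        If a mandatory column is missing from the header.
    """
    colmap = dict(CELLRANGER_DIALECT)
    if dialect:
        colmap.update(dialect)

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for fld in MANDATORY_FIELDS:
        if colmap[fld] not in df.columns:
            raise ContigFormatError(
                f"contig table {path} is missing mandatory column "
                f"{colmap[fld]!r} (field {fld!r})"
            )
    if df.empty:
        log.warning("contig table %s contains no data rows", path)
        return []

    def col(fld: str) -> pd.Series:
        name = colmap[fld]
        if name in df.columns:
            return df[name]
        return pd.Series([""] * len(df), index=df.index)

    records: list[ContigRecord] = []
    n_rejected = 0
    chains = col("chain")
    productives = col("productive")
    for i in df.index:
        prod = _parse_bool(productives[i])
        if prod is None:
            n_rejected += 1
            continue
        chain = chains[i].strip().upper()
        if chain not in TCR_CHAINS:
            chain = "other"
        try:
            umis = int(float(col("umis")[i] or 0))
            reads = int(float(col("reads")[i] or 0))
        except ValueError:
            n_rejected += 1
            continue
        records.append(
            ContigRecord(
                barcode=col("barcode")[i],
                chain=chain,
                cdr3_aa=col("cdr3_aa")[i],
                cdr3_nt=col("cdr3_nt")[i],
                v_gene=col("v_gene")[i],
                j_gene=col("j_gene")[i],
                productive=prod,
                umis=umis,
                reads=reads,
            )
        )
    if n_rejected:
        log.warning("%s: rejected %d unparseable rows", path, n_rejected)
    return records


def write_contig_table(records: list[ContigRecord], path) -> None:
    """Write records as a cellranger-vdj style contig annotation CSV."""
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "barcode": r.barcode,
                "is_cell": "True",
                "contig_id": f"{r.barcode}_contig_{i}",
                "high_confidence": "True",
                "chain": r.chain if r.chain in TCR_CHAINS else "Multi",
                "v_gene": r.v_gene,
                "d_gene": "None",
                "j_gene": r.j_gene,
                "c_gene": "None",
                "full_length": "True",
                "productive": "True" if r.productive else "False",
                "cdr3": r.cdr3_aa,
                "cdr3_nt": r.cdr3_nt,
                "reads": r.reads,
                "umis": r.umis,
                "raw_clonotype_id": "None",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def assemble_clonotypes(
    contigs: list[ContigRecord],
    key_level: str = "nt",
    chain_policy: ChainPolicy | None = None,
) -> list[CellClonotype]:
    """Assemble per-cell clonotype keys from productive contigs.

    Per barcode and locus, productive contigs with a non-empty CDR3 at the
    requested level are ranked by (UMIs desc, reads desc, cdr3_nt asc) and at
    most ``chain_policy.max_per_locus`` retained. The clonotype key is the
    sorted ``chain:CDR3`` concatenation over retained chains, so it is
    independent of input row order. Barcodes with no retained chain (or no
    TRB under ``require_trb``) are dropped and counted in the log.
    """
    if key_level not in ("nt", "aa"):
        raise ValueError(f"key_level must be 'nt' or 'aa', got {key_level!r}")
    policy = chain_policy or ChainPolicy()
    suffix_re = re.compile(policy.barcode_suffix) if policy.barcode_suffix else None

    by_barcode: dict[str, list[ContigRecord]] = {}
    order: list[str] = []
    for r in contigs:
        if not r.productive:
            continue
        cdr3 = r.cdr3_nt if key_level == "nt" else r.cdr3_aa
        if not cdr3 or r.chain not in TCR_CHAINS:
            continue
        bc = suffix_re.sub("", r.barcode) if suffix_re else r.barcode
        if bc not in by_barcode:
            by_barcode[bc] = []
            order.append(bc)
        by_barcode[bc].append(r)

    cells: list[CellClonotype] = []
    n_dropped = 0
    for bc in order:
        retained: list[ContigRecord] = []
        for locus in TCR_CHAINS:
            locus_contigs = sorted(
                (c for c in by_barcode[bc] if c.chain == locus),
                key=lambda c: (-c.umis, -c.reads, c.cdr3_nt),
            )
            # duplicate assemblies of one chain (same CDR3) collapse to the
            # best-supported contig; a clonotype is a set of distinct chains
            kept, seen_cdr3 = [], set()
            for c in locus_contigs:
                cdr3 = c.cdr3_nt if key_level == "nt" else c.cdr3_aa
                if cdr3 in seen_cdr3:
                    continue
                seen_cdr3.add(cdr3)
                kept.append(c)
                if len(kept) == policy.max_per_locus:
                    break
            retained.extend(kept)
        n_tra = sum(1 for c in retained if c.chain == "TRA")
        n_trb = sum(1 for c in retained if c.chain == "TRB")
        if not retained or (policy.require_trb and n_trb == 0):
            n_dropped += 1
            continue
        parts = sorted(
            f"{c.chain}:{c.cdr3_nt if key_level == 'nt' else c.cdr3_aa}"
            for c in retained
        )
        # representative beta CDR3 (aa); alpha fallback for beta-less cells
        trbs = [c for c in retained if c.chain == "TRB"]
        rep = trbs[0] if trbs else retained[0]
        cells.append(
            CellClonotype(
                barcode=bc,
                clonotype_key="|".join(parts),
                n_tra=n_tra,
                n_trb=n_trb,
                cdr3b_aa=rep.cdr3_aa,
            )
        )
    if n_dropped:
        log.info("dropped %d barcodes with no retained chains", n_dropped)
    return cells


def write_cell_table(cells: list[CellClonotype], path) -> None:
    """Write the per-cell clonotype assignment as TSV."""
    pd.DataFrame(
        {
            "barcode": [c.barcode for c in cells],
            "clonotype_key": [c.clonotype_key for c in cells],
            "n_tra": [c.n_tra for c in cells],
            "n_trb": [c.n_trb for c in cells],
            "cdr3b_aa": [c.cdr3b_aa for c in cells],
        }
    ).to_csv(path, sep="\t", index=False)
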