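"""Synthetic paired-timepoint cohorts with known clonal ground truth.

Emulates the study design this package analyzes: patients sampled before and
after immunosuppressive therapy, plus single-timepoint healthy donors. Each
patient's baseline repertoire draws clone sizes from a heavy-tailed power law
(healthy donors from a near-uniform Dirichlet), plants treatment-sensitive
(fold < 0.5), treatment-resistant (fold > 2) and stable clones at configured
frequency budgets, and adds post-treatment-only "new" clones whose summed
frequency (the new-clone burden) varies across patients. Blood counts are
generated so that hematopoietic recovery is negatively coupled to new-clone
burden, which is the planted signal the therapeutic index should detect.

Cells are drawn multinomially from the clone frequency vectors and emitted as
cellranger-vdj style contig CSVs (1 productive TRA + 1 productive TRB per
cell; some clones carry a genuine second TRA chain; a configurable rate of
decoy contigs — non-productive chains and duplicate assemblies — exercises
parser filtering). Every output is a pure function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import zipf

from tcrdyn.clonotype import CloneTable
from tcrdyn.contig_io import ContigRecord, write_contig_table

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Standard codon table (stop codons omitted; CDR3s are coding sequence).
CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}


@dataclass(frozen=True)
class PlantedFractions:
    """Per-patient frequency budgets for planted clone classes.

    ``new`` is the mean new-clone burden; the per-patient burden is drawn
    uniformly in ``new +/- CohortConfig.new_frac_jitter`` so that the burden
    varies across the cohort (otherwise the therapeutic index would have no
    signal to detect).
    """

    sensitive: float = 0.12
    resistant: float = 0.04
    stable: float = 0.06
    new: float = 0.15


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_patients: int = 16
    n_healthy: int = 4
    cells_per_sample: int = 2000
    clone_size_law: str = "power_law"  # or "dirichlet"
    power_exponent: float = 2.5
    n_clones: int = 8000
    healthy_n_clones: int = 8000
    healthy_dirichlet_alpha: float = 1.0
    planted: PlantedFractions = field(default_factory=PlantedFractions)
    fold_sensitive: float = 0.25
    fold_resistant: float = 4.0
    new_frac_jitter: float = 0.12
    n_new_clones: int = 30
    new_clone_relatedness: float = 0.5
    second_tra_rate: float = 0.05
    decoy_rate: float = 0.05
    recovery_intercept: float = 2.0
    recovery_coupling: float = -8.0
    recovery_noise_sd: float = 0.5
    analyte_jitter_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.planted
        budget = p.sensitive + p.resistant + p.stable + p.new + self.new_frac_jitter
        if budget > 1.0:
            raise ValueError(f"planted frequency budgets sum to {budget:.3f} > 1")
        if self.cells_per_sample < 100:
            raise ValueError("cells_per_sample must be >= 100")
        if self.clone_size_law not in ("power_law", "dirichlet"):
            raise ValueError(f"unknown clone_size_law {self.clone_size_law!r}")


@dataclass
class CloneTruth:
    """Ground truth for one simulated clone."""

    cdr3a_aa: str
    cdr3b_aa: str
    cdr3a_nt: str
    cdr3b_nt: str
    cdr3a2_aa: str = ""  # second TRA chain (some clones genuinely carry two)
    cdr3a2_nt: str = ""
    planted_class: str = "background"  # sensitive/resistant/stable/background/new
    origin: str = "pre_existing"  # or "new"
    pre_freq: float = 0.0
    post_freq: float = 0.0
    uid: int = 0  # stable index; keys clones generated without sequences

    def clonotype_key(self, level: str = "nt") -> str:
        """Clonotype key this clone's cells will assemble to."""
        if not self.cdr3b_nt:
            return f"clone:{self.uid}"
        if level == "nt":
            parts = [f"TRA:{self.cdr3a_nt}", f"TRB:{self.cdr3b_nt}"]
            if self.cdr3a2_nt:
                parts.append(f"TRA:{self.cdr3a2_nt}")
        else:
            parts = [f"TRA:{self.cdr3a_aa}", f"TRB:{self.cdr3b_aa}"]
            if self.cdr3a2_aa:
                parts.append(f"TRA:{self.cdr3a2_aa}")
        return "|".join(sorted(parts))


@dataclass
class PatientTruth:
    """Planted ground truth for one simulated patient (or healthy donor)."""

    patient_id: str
    clones: list[CloneTruth]
    new_clone_burden: float = 0.0  # planted summed post frequency of new clones
    true_recovery: float = 0.0  # recovery score before analyte-level noise
    paired: bool = True

    def pre_freqs(self) -> np.ndarray:
        return np.array([c.pre_freq for c in self.clones])

    def post_freqs(self) -> np.ndarray:
        return np.array([c.post_freq for c in self.clones])


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *stream]))


def _random_cdr3_aa(rng: np.random.Generator, chain: str) -> str:
    length = int(np.clip(round(rng.normal(13.0, 2.0)), 8, 20))
    prefix = "CASS" if chain == "TRB" else "CAV"
    middle = "".join(
        AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), length - len(prefix) - 1)
    )
    return prefix + middle + "F"


def _reverse_translate(rng: np.random.Generator, aa: str) -> str:
    return "".join(CODONS[c][rng.integers(0, len(CODONS[c]))] for c in aa)


def _mutate_one(rng: np.random.Generator, aa: str) -> str:
    """Single amino-acid substitution at an internal position."""
    pos = int(rng.integers(1, len(aa) - 1))
    old = aa[pos]
    new = old
    while new == old:
        new = AA_ALPHABET[rng.integers(0, len(AA_ALPHABET))]
    return aa[:pos] + new + aa[pos + 1 :]


def _draw_frequencies(cfg: CohortConfig, rng: np.random.Generator, healthy: bool) -> np.ndarray:
    if healthy:
        freqs = rng.dirichlet(np.full(cfg.healthy_n_clones, cfg.healthy_dirichlet_alpha))
        return freqs
    if cfg.clone_size_law == "power_law":
        sizes = zipf.rvs(cfg.power_exponent, size=cfg.n_clones, random_state=rng)
        sizes = np.minimum(sizes, cfg.cells_per_sample).astype(float)
        return sizes / sizes.sum()
    freqs = rng.dirichlet(np.full(cfg.n_clones, cfg.healthy_dirichlet_alpha))
    return freqs


def _make_sequences(
    cfg: CohortConfig, rng: np.random.Generator, n: int, seen: set
) -> list[CloneTruth]:
    """Generate ``n`` clones with unique chain sequences."""
    clones = []
    for _ in range(n):
        while True:
            a_aa = _random_cdr3_aa(rng, "TRA")
            b_aa = _random_cdr3_aa(rng, "TRB")
            a_nt = _reverse_translate(rng, a_aa)
            b_nt = _reverse_translate(rng, b_aa)
            if (a_nt, b_nt) not in seen and a_nt != b_nt:
                seen.add((a_nt, b_nt))
                break
        clone = CloneTruth(cdr3a_aa=a_aa, cdr3b_aa=b_aa, cdr3a_nt=a_nt, cdr3b_nt=b_nt)
        if rng.random() < cfg.second_tra_rate:
            a2_aa = _random_cdr3_aa(rng, "TRA")
            clone.cdr3a2_aa = a2_aa
            clone.cdr3a2_nt = _reverse_translate(rng, a2_aa)
        clones.append(clone)
    return clones


def simulate_patient_truth(
    cfg: CohortConfig, patient_index: int, with_sequences: bool = True
) -> PatientTruth:
    """Plant one patient's paired clone-frequency ground truth.

    Baseline frequencies come from the configured clone-size law. Planted
    classes are assigned walking clones from largest to smallest, filling the
    class budgets roughly proportionally; remaining clones are unplanted
    background with fold effect 1. Post-treatment frequencies apply the fold
    effects, renormalize the pre-existing compartment to (1 - burden), and add
    the new-clone compartment at the drawn burden.

    ``with_sequences=False`` skips CDR3 generation (clones get synthetic index
    keys) for count-level simulation loops that never emit contig files.
    """
    rng = _rng(cfg.seed, 1, patient_index)
    freqs = _draw_frequencies(cfg, rng, healthy=False)
    n = freqs.size

    seen: set = set()
    if with_sequences:
        clones = _make_sequences(cfg, rng, n, seen)
    else:
        clones = [CloneTruth("", "", "", "") for _ in range(n)]
    for clone, f in zip(clones, freqs):
        clone.pre_freq = float(f)

    # plant classes on the largest clones, filling budgets proportionally
    p = cfg.planted
    initial = {"sensitive": p.sensitive, "resistant": p.resistant, "stable": p.stable}
    remaining = dict(initial)
    min_plant_freq = 3.0 / cfg.cells_per_sample
    for idx in np.argsort(-freqs):
        f = float(freqs[idx])
        if f < min_plant_freq:
            break
        cands = [c for c, r in remaining.items() if initial[c] > 0 and r >= 0.5 * f]
        if not cands:
            continue
        pick = max(cands, key=lambda c: remaining[c] / initial[c])
        clones[idx].planted_class = pick
        remaining[pick] -= f

    burden = p.new + float(rng.uniform(-cfg.new_frac_jitter, cfg.new_frac_jitter))
    burden = float(np.clip(burden, 0.0, 0.95))
    fold = {"sensitive": cfg.fold_sensitive, "resistant": cfg.fold_resistant}
    post_unnorm = np.array(
        [c.pre_freq * fold.get(c.planted_class, 1.0) for c in clones]
    )
    post_pre_existing = post_unnorm / post_unnorm.sum() * (1.0 - burden)
    for clone, f in zip(clones, post_pre_existing):
        clone.post_freq = float(f)

    # new clones: present only post-treatment; a configurable share are
    # single-substitution variants of pre-existing clones (shared-antigen-like)
    if burden > 0 and cfg.n_new_clones > 0:
        new_sizes = zipf.rvs(2.0, size=cfg.n_new_clones, random_state=rng).astype(float)
        new_freqs = new_sizes / new_sizes.sum() * burden
        if with_sequences:
            new_clones = _make_sequences(cfg, rng, cfg.n_new_clones, seen)
        else:
            new_clones = [CloneTruth("", "", "", "") for _ in range(cfg.n_new_clones)]
        for nc, f in zip(new_clones, new_freqs):
            nc.planted_class = "new"
            nc.origin = "new"
            nc.post_freq = float(f)
            if with_sequences and rng.random() < cfg.new_clone_relatedness:
                parent = clones[int(rng.integers(0, n))]
                while True:
                    b_aa = _mutate_one(rng, parent.cdr3b_aa)
                    b_nt = _reverse_translate(rng, b_aa)
                    if (nc.cdr3a_nt, b_nt) not in seen:
                        seen.add((nc.cdr3a_nt, b_nt))
                        break
                nc.cdr3b_aa = b_aa
                nc.cdr3b_nt = b_nt
        clones = clones + new_clones

    for uid, clone in enumerate(clones):
        clone.uid = uid
    return PatientTruth(
        patient_id=f"P{patient_index + 1:02d}",
        clones=clones,
        new_clone_burden=burden,
    )


def simulate_healthy_truth(cfg: CohortConfig, donor_index: int) -> PatientTruth:
    """Single-timepoint healthy-donor repertoire (near-uniform clone sizes)."""
    rng = _rng(cfg.seed, 5, donor_index)
    freqs = _draw_frequencies(cfg, rng, healthy=True)
    clones = _make_sequences(cfg, rng, freqs.size, set())
    for clone, f in zip(clones, freqs):
        clone.pre_freq = float(f)
        clone.planted_class = "background"
    return PatientTruth(
        patient_id=f"HD{donor_index + 1:02d}", clones=clones, paired=False
    )


def sample_pair_counts(
    cfg: CohortConfig, truth: PatientTruth, patient_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial cell counts (pre, post) aligned to ``truth.clones``."""
    rng = _rng(cfg.seed, 2, patient_index)
    pre = rng.multinomial(cfg.cells_per_sample, truth.pre_freqs())
    post = rng.multinomial(cfg.cells_per_sample, truth.post_freqs())
    return pre, post


def counts_to_clone_table(
    truth: PatientTruth, counts: np.ndarray, sample_id: str, level: str = "nt"
) -> CloneTable:
    """Clone table implied by ground-truth clones and sampled counts."""
    table_counts: dict[str, int] = {}
    meta: dict[str, str] = {}
    for clone, c in zip(truth.clones, counts):
        if c > 0:
            key = clone.clonotype_key(level)
            table_counts[key] = table_counts.get(key, 0) + int(c)
            meta.setdefault(key, clone.cdr3b_aa)
    if not table_counts:
        raise ValueError(f"sample {sample_id!r} drew zero cells")
    return CloneTable(sample_id=sample_id, counts=table_counts, key_level=level, meta=meta)


def _barcode(i: int) -> str:
    digits = np.base_repr(i, base=4).zfill(8)
    return "AAAAAAAA" + "".join("ACGT"[int(d)] for d in digits) + "-1"


def contig_records_for_sample(
    cfg: CohortConfig,
    truth: PatientTruth,
    counts: np.ndarray,
    rng: np.random.Generator,
) -> list[ContigRecord]:
    """Emit per-cell contig records for one sampled repertoire."""
    records: list[ContigRecord] = []
    cell_idx = 0
    for clone_idx, (clone, c) in enumerate(zip(truth.clones, counts)):
        v_b, j_b = f"TRBV{clone_idx % 28 + 1}", f"TRBJ{clone_idx % 13 + 1}"
        v_a, j_a = f"TRAV{clone_idx % 39 + 1}", f"TRAJ{clone_idx % 50 + 1}"
        for _ in range(int(c)):
            bc = _barcode(cell_idx)
            cell_idx += 1
            umis_b = int(rng.integers(3, 15))
            umis_a = int(rng.integers(1, 10))
            records.append(
                ContigRecord(bc, "TRB", clone.cdr3b_aa, clone.cdr3b_nt, v_b, j_b,
                             True, umis_b, umis_b * int(rng.integers(20, 40))))
            records.append(
                ContigRecord(bc, "TRA", clone.cdr3a_aa, clone.cdr3a_nt, v_a, j_a,
                             True, umis_a, umis_a * int(rng.integers(20, 40))))
            if clone.cdr3a2_nt:
                umis_a2 = max(1, umis_a - 1)
                records.append(
                    ContigRecord(bc, "TRA", clone.cdr3a2_aa, clone.cdr3a2_nt,
                                 v_a, j_a, True, umis_a2,
                                 umis_a2 * int(rng.integers(20, 40))))
            if rng.random() < cfg.decoy_rate:
                if rng.random() < 0.5:
                    # non-productive rearrangement: dropped by the parser filter
                    records.append(
                        ContigRecord(bc, "TRB", "", "", v_b, j_b, False, 1, 25))
                else:
                    # duplicate assembly of the same chain at lower UMI support
                    records.append(
                        ContigRecord(bc, "TRB", clone.cdr3b_aa, clone.cdr3b_nt,
                                     v_b, j_b, True, 1, 20))
    return records


def generate_repertoire_pair(
    cfg: CohortConfig, patient_index: int, outdir
) -> tuple[Path, Path, PatientTruth]:
    """Write one patient's pre/post contig CSVs; return paths and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_patient_truth(cfg, patient_index)
    pre_counts, post_counts = sample_pair_counts(cfg, truth, patient_index)
    rng = _rng(cfg.seed, 3, patient_index)
    pre_path = outdir / f"{truth.patient_id}_pre_contigs.csv"
    post_path = outdir / f"{truth.patient_id}_post_contigs.csv"
    write_contig_table(contig_records_for_sample(cfg, truth, pre_counts, rng), pre_path)
    write_contig_table(contig_records_for_sample(cfg, truth, post_counts, rng), post_path)
    return pre_path, post_path, truth


def generate_healthy_sample(
    cfg: CohortConfig, donor_index: int, outdir
) -> tuple[Path, PatientTruth]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_healthy_truth(cfg, donor_index)
    rng = _rng(cfg.seed, 6, donor_index)
    counts = rng.multinomial(cfg.cells_per_sample, truth.pre_freqs())
    path = outdir / f"{truth.patient_id}_pre_contigs.csv"
    write_contig_table(contig_records_for_sample(cfg, truth, counts, rng), path)
    return path, truth


#: Reference blood-count distributions (per-uL units), healthy-population scale.
DEFAULT_REFERENCE = {
    "anc": (3500.0, 1200.0),
    "plt": (250_000.0, 60_000.0),
    "arc": (60_000.0, 20_000.0),
}


def generate_blood_counts(
    cfg: CohortConfig, truths: list[PatientTruth]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate paired blood counts coupled to each patient's new-clone burden.

    Pre-treatment counts sit far below the reference median (severe-disease
    regime). The post-treatment change of each patient's mean analyte z-score
    is ``intercept + coupling * new_clone_burden + noise``; with the default
    negative coupling, patients acquiring a larger new-clone burden recover
    less. Sets ``truth.true_recovery`` (pre-noise recovery) on each truth.
    """
    rng = _rng(cfg.seed, 4)
    rows = []
    for truth in truths:
        if not truth.paired:
            continue
        z_pre = rng.normal(-2.4, 0.25, size=3)
        recovery = (
            cfg.recovery_intercept
            + cfg.recovery_coupling * truth.new_clone_burden
            + float(rng.normal(0.0, cfg.recovery_noise_sd))
        )
        truth.true_recovery = recovery
        z_post = z_pre + recovery + rng.normal(0.0, cfg.analyte_jitter_sd, size=3)
        for tp, z in (("pre", z_pre), ("post", z_post)):
            row = {"patient_id": truth.patient_id, "timepoint": tp}
            for (analyte, (med, sd)), zi in zip(DEFAULT_REFERENCE.items(), z):
                row[analyte] = max(round(med + zi * sd, 1), 0.0)
            rows.append(row)
    blood = pd.DataFrame(rows)
    reference = pd.DataFrame(
        [
            {"analyte": a, "median": med, "sd": sd}
            for a, (med, sd) in DEFAULT_REFERENCE.items()
        ]
    )
    return blood, reference


@dataclass
class CohortPaths:
    outdir: Path
    manifest: Path
    blood_counts: Path
    reference: Path
    ground_truth: Path
    truths: list[PatientTruth]


def generate_cohort(cfg: CohortConfig, outdir) -> CohortPaths:
    """Generate the full cohort: contig CSVs, manifest, blood counts, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truths: list[PatientTruth] = []
    for i in range(cfg.n_patients):
        pre_path, post_path, truth = generate_repertoire_pair(cfg, i, outdir)
        truths.append(truth)
        manifest_rows.append(
            {"patient_id": truth.patient_id, "timepoint": "pre",
             "path": pre_path.name, "cohort": "patient"})
        manifest_rows.append(
            {"patient_id": truth.patient_id, "timepoint": "post",
             "path": post_path.name, "cohort": "patient"})
    for i in range(cfg.n_healthy):
        path, truth = generate_healthy_sample(cfg, i, outdir)
        truths.append(truth)
        manifest_rows.append(
            {"patient_id": truth.patient_id, "timepoint": "pre",
             "path": path.name, "cohort": "hd"})

    blood, reference = generate_blood_counts(cfg, truths)
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest, sep="\t", index=False)
    blood_path = outdir / "blood_counts.tsv"
    blood.to_csv(blood_path, sep="\t", index=False, float_format="%.1f")
    ref_path = outdir / "reference.tsv"
    reference.to_csv(ref_path, sep="\t", index=False, float_format="%.1f")

    truth_path = outdir / "ground_truth.json"
    payload = {
        t.patient_id: {
            "paired": t.paired,
            "new_clone_burden": t.new_clone_burden,
            "true_recovery": t.true_recovery,
            "clones": [
                {
                    "key": c.clonotype_key("nt"),
                    "cdr3b_aa": c.cdr3b_aa,
                    "planted_class": c.planted_class,
                    "origin": c.origin,
                    "pre_freq": c.pre_freq,
                    "post_freq": c.post_freq,
                }
                for c in t.clones
            ],
        }
        for t in truths
    }
    truth_path.write_text(json.dumps(payload, indent=None, sort_keys=True))
    return CohortPaths(
        outdir=outdir,
        manifest=manifest,
        blood_counts=blood_path,
        reference=ref_path,
        ground_truth=truth_path,
        truths=truths,
    )
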