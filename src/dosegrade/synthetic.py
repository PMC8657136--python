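"""Synthetic data generator for the dose-graded MYC induction design.

Emulates the statistical structure the downstream stages assume: negative-
binomial counts for 3 genotypes (WT, T58A, T58I) x 7 doxycycline doses x
replicates, gene-wise monotone Hill dose-response curves whose half-maximal
dose (EC50) and amplitude can differ by genotype for a labelled subset of
genes, a biotype/length-structured annotation, and a genome in which
canonical E-box motifs (CACGTG) are planted at controlled distances from
transcription start sites.

All randomness flows from a single seed through named sub-generators so a
fixed :class:`SimulationConfig` yields byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "T58A", "T58I")
MUTANTS = ("T58A", "T58I")
DEFAULT_DOSES = (0.0, 25.0, 50.0, 100.0, 300.0, 600.0, 1000.0)
EBOX = "CACGTG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dose-response study.

    Doses are ng/mL doxycycline; baseline means are on the natural-log read
    scale; amplitudes are log2 units spanned by the full dose range; the
    gene-wise NB dispersion is Gamma(shape, rate) distributed unless pinned
    with ``dispersion_fixed``.
    """

    n_genes: int = 2000
    frac_regulated: float = 0.30
    frac_mutant_differential: float = 0.06
    doses: tuple = DEFAULT_DOSES
    n_replicates: int = 3
    baseline_log_mean_range: tuple = (3.0, 7.5)
    amplitude_range: tuple = (1.0, 3.0)
    ec50_by_genotype: dict = field(
        default_factory=lambda: {"WT": 150.0, "T58A": 25.0, "T58I": 600.0}
    )
    hill_slope: float = 2.5
    dispersion_shape: float = 2.0
    dispersion_rate: float = 20.0
    dispersion_fixed: float | None = None
    library_size_range: tuple = (8e6, 1.5e7)
    frac_noncoding: float = 0.15
    gene_length_log_mean: float = 7.3  # ln bp; median ~1.5 kb
    gene_length_log_sd: float = 0.7
    motif_distance_scheme: dict = field(
        default_factory=lambda: {
            "up": (0, 500),
            "down": None,
            "unregulated": (1500, 4000),
        }
    )
    flank_bp: int = 5000
    mutant_amplitude_boost: float = 2.0
    frac_mutant_only: float = 0.3
    rng_seed: int = 0

    def validate(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        if sorted(doses) != list(doses) or 0.0 not in doses:
            raise ValueError("doses must be sorted ascending and include 0")
        for name in ("frac_regulated", "frac_mutant_differential",
                     "frac_noncoding", "frac_mutant_only"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(v <= 0 for v in self.ec50_by_genotype.values()):
            raise ValueError("EC50 values must be positive")
        if self.n_replicates < 1:
            # single-replicate designs can be laid out, but dispersion
            # estimation downstream requires >= 2 replicates per condition
            raise ValueError("n_replicates must be >= 1")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be positive")


def _sub_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# design and ground truth
# ---------------------------------------------------------------------------

def simulate_design(config: SimulationConfig) -> pd.DataFrame:
    """One sample per genotype x dose x replicate, genotype-major order."""
    config.validate()
    rows = []
    for g in GENOTYPES:
        for d in config.doses:
            for r in range(1, config.n_replicates + 1):
                rows.append({
                    "sample_id": f"{g}_d{int(d)}_r{r}",
                    "genotype": g,
                    "dose": float(d),
                    "replicate": r,
                })
    return pd.DataFrame(rows)


def simulate_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene ground truth: regulation, per-genotype amplitude/EC50,
    differential-mutant membership, biotype, length and dispersion."""
    n = config.n_genes
    gene_ids = [f"G{i:06d}" for i in range(1, n + 1)]
    regulated = rng.random(n) < config.frac_regulated
    direction = np.where(rng.random(n) < 0.5, "up", "down")
    direction = np.where(regulated, direction, "")
    amp = rng.uniform(*config.amplitude_range, size=n)
    sign = np.where(direction == "down", -1.0, 1.0)
    base_amp = np.where(regulated, sign * amp, 0.0)

    # differential genes: a subset of genes responds differently in a mutant
    diff = regulated & (rng.random(n) < (
        config.frac_mutant_differential / max(config.frac_regulated, 1e-12)))
    which = rng.random(n)
    diff_t58a = diff & (which < 0.45)
    diff_t58i = diff & (which >= 0.45) & (which < 0.90)
    diff_both = diff & (which >= 0.90)
    diff_t58a |= diff_both
    diff_t58i |= diff_both
    # some differential genes are regulated only in the mutant (the
    # mutant-only regions of the three-way selection Venn)
    mutant_only = diff & (rng.random(n) < config.frac_mutant_only)

    wt_ec50 = config.ec50_by_genotype["WT"]
    truth = pd.DataFrame({"gene_id": gene_ids, "regulated": regulated,
                          "direction": direction})
    for g in GENOTYPES:
        a = base_amp.copy()
        e = np.full(n, wt_ec50)
        if g in MUTANTS:
            is_diff = diff_t58a if g == "T58A" else diff_t58i
            a = np.where(is_diff, a * config.mutant_amplitude_boost, a)
            e = np.where(is_diff, config.ec50_by_genotype[g], e)
        else:
            a = np.where(mutant_only, 0.0, a)
        truth[f"amplitude_{g}"] = a
        truth[f"ec50_{g}"] = e
    truth["diff_t58a"] = diff_t58a
    truth["diff_t58i"] = diff_t58i
    truth["baseline_log_mean"] = rng.uniform(*config.baseline_log_mean_range, size=n)
    if config.dispersion_fixed is not None:
        truth["dispersion"] = float(config.dispersion_fixed)
    else:
        truth["dispersion"] = rng.gamma(config.dispersion_shape, size=n) / config.dispersion_rate
    truth["biotype"] = np.where(rng.random(n) < config.frac_noncoding,
                                "non_coding", "protein_coding")
    length = np.exp(rng.normal(config.gene_length_log_mean,
                               config.gene_length_log_sd, size=n))
    truth["length_bp"] = np.clip(length, 200, 20000).round().astype(int)
    label = np.where(regulated, direction, "unregulated")
    truth["motif_label"] = label
    truth["member_sets"] = ""
    return truth


# ---------------------------------------------------------------------------
# dose-response means and counts
# ---------------------------------------------------------------------------

def hill(dose, ec50, slope):
    """Hill occupancy h(d) = d^s / (d^s + EC50^s); h(0)=0, h(EC50)=1/2."""
    ec50 = np.asarray(ec50, dtype=float)
    if np.any(ec50 <= 0):
        raise ValueError("EC50 must be positive")
    d = np.asarray(dose, dtype=float)
    with np.errstate(invalid="ignore"):
        num = np.power(d, slope)
        out = num / (num + np.power(ec50, slope))
    return np.where(d == 0, 0.0, out)


def dose_response_mean(baseline_log_mean, amplitude, ec50, dose, hill_slope):
    """Expected read-scale count before library scaling:
    exp(baseline) * 2^(amplitude * h(dose))."""
    h = hill(dose, ec50, hill_slope)
    return np.exp(np.asarray(baseline_log_mean, dtype=float)) * np.power(
        2.0, np.asarray(amplitude, dtype=float) * h)


def expected_means(truth: pd.DataFrame, design: pd.DataFrame,
                   config: SimulationConfig) -> pd.DataFrame:
    """Genes x samples matrix of expected read-scale counts (no library factor)."""
    n = len(truth)
    means = np.empty((n, len(design)))
    for j, row in enumerate(design.itertuples(index=False)):
        g = row.genotype
        means[:, j] = dose_response_mean(
            truth["baseline_log_mean"].to_numpy(),
            truth[f"amplitude_{g}"].to_numpy(),
            truth[f"ec50_{g}"].to_numpy(),
            row.dose, config.hill_slope)
    return pd.DataFrame(means, index=truth["gene_id"].to_numpy(),
                        columns=design["sample_id"].to_numpy())


def nb_draw(rng: np.random.Generator, mean, dispersion):
    """NB counts with var = mean + dispersion * mean^2 (Poisson as dispersion->0)."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.maximum(np.asarray(dispersion, dtype=float), 1e-12)
    r = 1.0 / alpha
    p = r / (r + np.maximum(mean, 0.0))
    out = rng.negative_binomial(r, p)
    return np.where(mean <= 0, 0, out)


def sample_counts(means: pd.DataFrame, truth: pd.DataFrame,
                  config: SimulationConfig, rng: np.random.Generator
                  ) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the count matrix; returns (counts, drawn library sizes).

    Library sizes are log-uniform over ``library_size_range`` and enter as a
    multiplicative factor relative to the geometric-mean library.
    """
    lo, hi = config.library_size_range
    libsizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=means.shape[1]))
    factor = libsizes / np.exp(np.mean(np.log(libsizes)))
    mu = means.to_numpy() * factor[None, :]
    alpha = truth["dispersion"].to_numpy()[:, None]
    counts = nb_draw(rng, mu, alpha)
    return (pd.DataFrame(counts, index=means.index, columns=means.columns),
            pd.Series(libsizes, index=means.columns, name="library_size"))


# ---------------------------------------------------------------------------
# genome with planted E-boxes
# ---------------------------------------------------------------------------

def _find_all(seq: bytes, motif: bytes) -> list[int]:
    pos, out = seq.find(motif), []
    while pos != -1:
        out.append(pos)
        pos = seq.find(motif, pos + 1)
    return out


def simulate_genome(config: SimulationConfig, truth: pd.DataFrame,
                    rng: np.random.Generator
                    ) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Build a single-chromosome genome whose only CACGTG occurrences are the
    planted ones, plus a matching gene annotation.

    Returns (genome {chrom: sequence str}, annotation, planted motif table).
    Genes are laid end to end with ``flank_bp`` of private flank on each side;
    planted distances must stay below ``flank_bp`` so each gene's own motif is
    its nearest.
    """
    n = len(truth)
    lengths = truth["length_bp"].to_numpy()
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    starts = np.empty(n, dtype=int)
    cursor = 0
    for i in range(n):
        starts[i] = cursor + config.flank_bp
        cursor = starts[i] + lengths[i] + config.flank_bp
    total = int(cursor)
    ends = starts + lengths
    tss = np.where(strands == "+", starts, ends - 1)

    # planted motif midpoints, by truth label
    scheme = config.motif_distance_scheme
    planted_mid = np.full(n, -1, dtype=int)
    dist = np.full(n, -1, dtype=int)
    for i in range(n):
        req = scheme.get(truth["motif_label"].iloc[i])
        if req is None:
            continue
        lo, hi = (req, req) if np.isscalar(req) else req
        d = int(rng.integers(lo, hi + 1))
        if d > config.flank_bp - 4:
            raise ValueError(
                f"requested motif distance {d} exceeds flank {config.flank_bp}; "
                "impossible placement")
        mid = tss[i] + d if strands[i] == "+" else tss[i] - d
        planted_mid[i] = mid
        dist[i] = d

    seq = bytearray(_BASES[rng.integers(0, 4, size=total, dtype=np.int64)].tobytes())
    motif = EBOX.encode()

    # scrub accidental E-boxes from the background (rejection-resample)
    for _ in range(100):
        hits = _find_all(bytes(seq), motif)
        if not hits:
            break
        for h in hits:
            seq[h + 2] = int(rng.choice(_BASES[[0, 3, 2]]))  # C -> A/T/G
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not scrub background E-boxes")

    planted_starts = set()
    for mid in planted_mid[planted_mid >= 0]:
        s = int(mid) - 3
        seq[s:s + 6] = motif
        planted_starts.add(s)

    # planting can create spurious occurrences straddling a planted site
    protected = np.zeros(total, dtype=bool)
    for s in planted_starts:
        protected[s:s + 6] = True
    for _ in range(100):
        extra = [h for h in _find_all(bytes(seq), motif) if h not in planted_starts]
        if not extra:
            break
        for h in extra:
            for off in range(6):
                if not protected[h + off]:
                    cur = seq[h + off]
                    choices = [b for b in _BASES.tolist() if b != cur]
                    seq[h + off] = int(rng.choice(choices))
                    break
    else:  # pragma: no cover
        raise RuntimeError("could not remove spurious E-boxes")

    annotation = pd.DataFrame({
        "gene_id": truth["gene_id"].to_numpy(),
        "chrom": "chr1",
        "start": starts,
        "end": ends,
        "strand": strands,
        "tss": tss,
        "length_bp": lengths,
        "biotype": truth["biotype"].to_numpy(),
    })
    planted = pd.DataFrame({
        "gene_id": truth["gene_id"].to_numpy(),
        "motif_midpoint": planted_mid,
        "planted_distance": dist,
    })
    return {"chr1": seq.decode("ascii")}, annotation, planted


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(truth: pd.DataFrame, config: SimulationConfig,
                       rng: np.random.Generator, set_size: int = 50,
                       n_controls: int = 5, enriched_frac: float = 0.8
                       ) -> dict[str, list[str]]:
    """Truth-enriched sets (80% drawn from a labelled truth category, rest
    uniform) plus uniform control sets."""
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    genes = truth["gene_id"].to_numpy()
    set_size = min(set_size, max(1, len(genes) // 4))
    categories = {
        "TRUTH_WT_REGULATED": truth["regulated"].to_numpy(),
        "TRUTH_T58A_SENSITIVE": truth["diff_t58a"].to_numpy(),
    }
    sets: dict[str, list[str]] = {}
    for name, mask in categories.items():
        pool = genes[mask]
        n_in = min(int(round(enriched_frac * set_size)), len(pool))
        if n_in == 0:
            continue
        members = list(rng.choice(pool, size=n_in, replace=False))
        rest = genes[~np.isin(genes, members)]
        members += list(rng.choice(rest, size=set_size - n_in, replace=False))
        sets[name] = sorted(members)
    for i in range(1, n_controls + 1):
        sets[f"CONTROL_{i}"] = sorted(rng.choice(genes, size=set_size, replace=False))
    member_sets = {g: [] for g in genes}
    for name, members in sets.items():
        for g in members:
            member_sets[g].append(name)
    truth["member_sets"] = [";".join(member_sets[g]) for g in genes]
    return sets


# ---------------------------------------------------------------------------
# orchestration + writers
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    design: pd.DataFrame
    truth: pd.DataFrame
    counts: pd.DataFrame
    library_sizes: pd.Series
    genome: dict | None
    annotation: pd.DataFrame | None
    planted: pd.DataFrame | None
    gene_sets: dict | None

    def write(self, outdir: str) -> list[str]:
        os.makedirs(outdir, exist_ok=True)
        written = []

        def _w(name, fn):
            path = os.path.join(outdir, name)
            fn(path)
            written.append(path)

        _w("counts.tsv", lambda p: self.counts.to_csv(p, sep="\t", index_label="gene_id"))
        _w("design.tsv", lambda p: self.design.to_csv(p, sep="\t", index=False))
        _w("truth.tsv", lambda p: self.truth.to_csv(p, sep="\t", index=False,
                                                    float_format="%.6g"))
        if self.genome is not None:
            _w("genome.fa", lambda p: write_fasta(self.genome, p))
            _w("genes.bed", lambda p: write_bed6(self.annotation, p))
            _w("genes.gtf", lambda p: write_gtf(self.annotation, p))
        if self.gene_sets is not None:
            _w("sets.gmt", lambda p: write_gmt(self.gene_sets, p))
        return written


def simulate(config: SimulationConfig, with_genome: bool = True,
             with_sets: bool = True) -> SimulatedDataset:
    """Run the whole generator from ``config.rng_seed``."""
    config.validate()
    r_truth, r_counts, r_genome, r_sets = _sub_rngs(config.rng_seed, 4)
    design = simulate_design(config)
    truth = simulate_truth(config, r_truth)
    means = expected_means(truth, design, config)
    counts, libsizes = sample_counts(means, truth, config, r_counts)
    genome = annotation = planted = None
    if with_genome:
        genome, annotation, planted = simulate_genome(config, truth, r_genome)
    gene_sets = simulate_gene_sets(truth, config, r_sets) if with_sets else None
    return SimulatedDataset(config, design, truth, counts, libsizes,
                            genome, annotation, planted, gene_sets)


def write_fasta(genome: dict, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed6(annotation: pd.DataFrame, path: str) -> None:
    bed = annotation[["chrom", "start", "end", "gene_id"]].copy()
    bed["score"] = 0
    bed["strand"] = annotation["strand"]
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_gtf(annotation: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}"; gene_biotype "{row.biotype}";'
            fh.write(f"{row.chrom}\tdosegrade\tgene\t{row.start + 1}\t{row.end}\t."
                     f"\t{row.strand}\t.\t{attrs}\n")


def write_gmt(sets: dict, path: str) -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, "synthetic"] + list(sets[name])) + "\n")


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
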