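"""Synthetic cohort generator with known ground truth.

Emulates the inputs of a gut plasmidome survey: a heavy-tailed regional pool
of plasmids, per-sample abundances drawn from the Sloan neutral model's beta
approximation, circular plasmid sequences carrying shared DNA blocks at a
controlled identity, bimodal plasmid lengths, mobilization-lifestyle and
pathway/AMR annotations, and disease/continent sample metadata.  Selected
(non-neutral) segments are planted by boosting their carriage probability
within a target disease group.  Every planted feature is recorded in a
ground-truth object so downstream recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import AbundanceMatrix

__all__ = [
    "SourcePool",
    "SimulationConfig",
    "GroundTruth",
    "make_source_pool",
    "simulate_neutral_abundances",
    "detect",
    "plant_selection",
    "generate_metadata",
    "generate_plasmid_sequences",
    "simulate_study",
]

# Cohort composition of the emulated survey: 1548 healthy, 339 IBD, 1035 GRD,
# 545 obese individuals across four continents.
DEFAULT_DISEASE_PROPORTIONS = {
    "healthy": 1548 / 3467,
    "IBD": 339 / 3467,
    "GRD": 1035 / 3467,
    "obese": 545 / 3467,
}
DEFAULT_CONTINENT_PROPORTIONS = {
    "Europe": 0.45,
    "NorthAmerica": 0.25,
    "Asia": 0.25,
    "Oceania": 0.05,
}

PATHWAY_VOCABULARY = (
    "beta-Lactam resistance",
    "ABC transporters",
    "Metabolic pathways",
    "Homologous recombination",
    "Mismatch repair",
    "Two-component system",
    "Vibrio cholerae infection",
)

_BASES = np.array(list("ACGT"))


@dataclass
class SourcePool:
    """Regional pool: entities dispersed in proportion to these weights."""

    entity_ids: np.ndarray
    p: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.entity_ids = np.asarray(self.entity_ids)
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p <= 0):
            raise ValueError("pool weights must be strictly positive")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("pool weights must sum to 1 within 1e-9")


@dataclass
class SimulationConfig:
    n_samples: int = 300
    Nm: float = 500.0
    d: float = 1e-3
    read_depth_range: tuple[int, int] = (20_000, 860_000)
    disease_proportions: dict = field(default_factory=lambda: dict(DEFAULT_DISEASE_PROPORTIONS))
    continent_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CONTINENT_PROPORTIONS))
    planted_selection: list = field(default_factory=list)  # (segment_id, disease, boost)
    lifestyle_fraction: float = 1027 / 11086
    # sequence generation
    n_plasmids: int = 60
    length_modes_bp: tuple[float, float] = (3_000.0, 30_000.0)
    length_weights: tuple[float, float] = (0.8, 0.2)
    length_sigma_log10: float = 0.15
    n_shared_blocks: int = 8
    block_length_range: tuple[int, int] = (1_200, 2_500)
    block_identity: float = 0.85
    block_carriers: int = 2
    origin_straddle_fraction: float = 0.25
    amr_base_rate: float = 0.05
    amr_odds_ratio: float = 6.14
    seed: int = 0

    def __post_init__(self) -> None:
        for name, props in (("disease", self.disease_proportions),
                            ("continent", self.continent_proportions)):
            if abs(sum(props.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} proportions must sum to 1")
        if self.Nm <= 0:
            raise ValueError("Nm must be positive")
        if not 0 < self.d < 1:
            raise ValueError("detection limit d must lie in (0, 1)")


@dataclass
class GroundTruth:
    neutral_flags: dict = field(default_factory=dict)       # entity -> bool
    planted_segments: dict = field(default_factory=dict)    # segment -> {disease, boost}
    segment_members: list = field(default_factory=list)     # (segment, plasmid, start, end, identity)
    lifestyles: dict = field(default_factory=dict)          # plasmid -> lifestyle
    annotations: dict = field(default_factory=dict)         # plasmid -> [labels]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def make_source_pool(n_entities: int, sigma: float = 2.0, seed: int = 0,
                     prefix: str = "E") -> SourcePool:
    """Heavy-tailed (log-normal) regional pool, renormalized to the simplex."""
    rng = np.random.default_rng(seed)
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n_entities)
    ids = np.array([f"{prefix}{i:05d}" for i in range(n_entities)])
    return SourcePool(ids, w / w.sum(), seed=seed)


def simulate_neutral_abundances(pool: SourcePool, cfg: SimulationConfig,
                                rng: np.random.Generator | None = None,
                                nominal_length_bp: float = 1_000.0,
                                read_length_bp: float = 150.0) -> AbundanceMatrix:
    """Draw per-sample abundances from the neutral model's beta approximation.

    For each sample, entity i's latent relative abundance is
    Beta(Nm*p_i, Nm*(1-p_i)); samples are renormalized to the simplex and
    integer read counts are drawn multinomially at the sample's read depth.
    Coverage fractions follow a Poisson per-base model at the implied depth.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    a = cfg.Nm * pool.p
    b = cfg.Nm * (1.0 - pool.p)
    if a.min() < 1e-8:
        raise ValueError(
            f"Nm*p underflows (min {a.min():.3g} < 1e-8); increase Nm or prune "
            "vanishingly rare pool entities before simulating")
    lat = rng.beta(a, b, size=(cfg.n_samples, len(pool.p)))
    lat /= lat.sum(axis=1, keepdims=True)
    lo, hi = cfg.read_depth_range
    depth = rng.integers(lo, hi + 1, size=cfg.n_samples)
    counts = rng.multinomial(depth, lat)
    abundance = counts / depth[:, None]
    lam = counts * read_length_bp / nominal_length_bp
    coverage = np.where(counts > 0, 1.0 - np.exp(-lam), 0.0)
    samples = pd.Index([f"S{i:05d}" for i in range(cfg.n_samples)], name="sample_id")
    cols = pd.Index(pool.entity_ids, name="entity_id")
    return AbundanceMatrix(
        abundance=pd.DataFrame(abundance, index=samples, columns=cols),
        coverage=pd.DataFrame(coverage, index=samples, columns=cols),
        read_depth=pd.Series(depth, index=samples, name="read_depth"),
    )


def detect(abund: AbundanceMatrix, d: float) -> pd.DataFrame:
    """Presence at the detection limit: relative abundance >= d."""
    return abund.abundance.ge(d)


def plant_selection(incidence: pd.DataFrame, metadata: pd.DataFrame,
                    cfg: SimulationConfig, truth: GroundTruth,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Boost carriage of planted segments within their target disease group.

    The within-group carriage probability of each planted segment is
    multiplied by its boost factor (capped at 1) by converting non-carriers
    to carriers at the top-up rate; all other cells are untouched.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    out = incidence.copy()
    diseases = set(metadata["disease"])
    for seg, disease, boost in cfg.planted_selection:
        if disease not in diseases:
            raise ValueError(f"unknown disease label {disease!r} for planted segment {seg}")
        if boost < 1:
            raise ValueError(f"boost factor must be >= 1, got {boost}")
        if seg not in out.columns:
            raise ValueError(f"planted segment {seg!r} not present in incidence")
        group = metadata.index[metadata["disease"] == disease]
        group = group.intersection(out.index)
        col = out.loc[group, seg].to_numpy(dtype=bool)
        base = col.mean()
        target = min(1.0, base * boost)
        if base < 1.0 and target > base:
            topup = (target - base) / (1.0 - base)
            flip = (~col) & (rng.random(len(col)) < topup)
            out.loc[group[flip], seg] = True
        truth.planted_segments[seg] = {"disease": disease, "boost": boost}
        truth.neutral_flags[seg] = False
    return out


def generate_metadata(cfg: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-sample disease and continent labels at configured proportions."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    samples = pd.Index([f"S{i:05d}" for i in range(cfg.n_samples)], name="sample_id")
    dis_labels = list(cfg.disease_proportions)
    cont_labels = list(cfg.continent_proportions)
    disease = rng.choice(dis_labels, size=cfg.n_samples,
                         p=list(cfg.disease_proportions.values()))
    continent = rng.choice(cont_labels, size=cfg.n_samples,
                           p=list(cfg.continent_proportions.values()))
    return pd.DataFrame({"disease": disease, "continent": continent}, index=samples)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases i.i.d. at the given rate (always to a different base)."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        codes = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(codes + shift) % 4]
    return out


def _write_circular(seq: np.ndarray, plasmid: np.ndarray, start: int) -> None:
    """Overwrite plasmid bases with ``seq`` starting at ``start``, wrapping."""
    L = len(plasmid)
    idx = (start + np.arange(len(seq))) % L
    plasmid[idx] = seq


def generate_plasmid_sequences(cfg: SimulationConfig, truth: GroundTruth | None = None,
                               rng: np.random.Generator | None = None):
    """Random circular plasmids with planted shared blocks and annotations.

    Lengths follow a two-component log-normal mixture (modes near 3 kb and
    30 kb, weights 0.8/0.2) reproducing the bimodal length distribution of
    gut plasmidomes.  Shared blocks are copied into ``block_carriers``
    plasmids with i.i.d. substitutions split evenly across copies so that
    pairwise identity matches ``block_identity``; a configurable fraction of
    copies straddles the linearization origin.  Lifestyle labels, mobility
    gene intervals, pathway labels and AMR counts are drawn with configurable
    odds between lifestyles.

    Returns (sequences, records, truth): a dict plasmid_id -> str, a
    DataFrame of per-plasmid annotations, and the updated ground truth.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    truth = truth if truth is not None else GroundTruth()

    comp = rng.choice(2, size=cfg.n_plasmids, p=list(cfg.length_weights))
    mu = np.log10(np.asarray(cfg.length_modes_bp))[comp]
    lengths = np.round(10 ** rng.normal(mu, cfg.length_sigma_log10)).astype(int)
    lengths = np.maximum(lengths, 1_000)
    ids = [f"P{i:04d}" for i in range(cfg.n_plasmids)]
    seqs = {pid: _random_seq(rng, L) for pid, L in zip(ids, lengths)}

    per_copy_rate = (1.0 - cfg.block_identity) / 2.0
    min_block = min(cfg.block_length_range)
    eligible = [pid for pid in ids if len(seqs[pid]) >= min_block + 200]
    rng.shuffle(eligible)
    free = list(eligible)
    for b in range(cfg.n_shared_blocks):
        blen = int(rng.integers(cfg.block_length_range[0], cfg.block_length_range[1] + 1))
        carriers = [pid for pid in free if len(seqs[pid]) >= blen + 200][:cfg.block_carriers]
        if len(carriers) < 2:
            raise ValueError(
                f"not enough plasmids of >= {blen + 200} bp to host shared block "
                f"{b}; increase n_plasmids or shrink block_length_range")
        for pid in carriers:
            free.remove(pid)
        master = _random_seq(rng, blen)
        seg_id = f"SEG{b:04d}"
        for pid in carriers:
            L = len(seqs[pid])
            copy = _mutate(rng, master, per_copy_rate)
            if rng.random() < cfg.origin_straddle_fraction:
                start = L - blen // 2
            else:
                start = int(rng.integers(0, max(L - blen, 1)))
            _write_circular(copy, seqs[pid], start)
            truth.segment_members.append(
                (seg_id, pid, int(start), int((start + blen) % L) if start + blen > L
                 else int(start + blen), cfg.block_identity))

    mobilizable = rng.random(cfg.n_plasmids) < cfg.lifestyle_fraction
    base_odds = cfg.amr_base_rate / (1 - cfg.amr_base_rate)
    mob_rate = base_odds * cfg.amr_odds_ratio / (1 + base_odds * cfg.amr_odds_ratio)
    rows = []
    for i, pid in enumerate(ids):
        L = int(lengths[i])
        lifestyle = "mobilizable" if mobilizable[i] else "non-mobilizable"
        truth.lifestyles[pid] = lifestyle
        intervals = []
        if mobilizable[i]:
            for _ in range(int(rng.integers(1, 4))):
                ilen = int(rng.integers(500, 2_001))
                if ilen < L:
                    s = int(rng.integers(0, L - ilen))
                    intervals.append((s, s + ilen))
        n_terms = int(rng.integers(0, 4))
        labels = sorted(rng.choice(PATHWAY_VOCABULARY, size=n_terms, replace=False))
        amr_rate = mob_rate if mobilizable[i] else cfg.amr_base_rate
        amr = int(rng.poisson(1.5)) + 1 if rng.random() < amr_rate else 0
        truth.annotations[pid] = list(labels)
        rows.append({
            "plasmid_id": pid, "length": L, "lifestyle": lifestyle,
            "pathways": ";".join(labels), "amr_count": amr,
            "mobility_intervals": ";".join(f"{s}-{e}" for s, e in intervals),
        })
    records = pd.DataFrame(rows).set_index("plasmid_id")
    sequences = {pid: "".join(arr) for pid, arr in seqs.items()}
    return sequences, records, truth


def write_fasta(sequences: dict, path) -> None:
    recs = [SeqRecord(Seq(s), id=pid, description="circular=true")
            for pid, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def simulate_study(cfg: SimulationConfig, outdir=None):
    """Full synthetic study: sequences, abundances, metadata, annotations, truth.

    Plasmid-level abundances are drawn from the neutral model; sample
    metadata and sequence-level ground truth are generated at the configured
    proportions.  If ``outdir`` is given, the standard input files
    (plasmids.fasta, abundance.tsv, coverage.tsv, read_depth.tsv,
    metadata.tsv, annotations.tsv, truth.json) are written there.
    """
    truth = GroundTruth()
    sequences, records, truth = generate_plasmid_sequences(cfg, truth)
    pool = make_source_pool(cfg.n_plasmids, seed=cfg.seed, prefix="P")
    pool = SourcePool(np.array(list(sequences)), pool.p, seed=cfg.seed)
    abund = simulate_neutral_abundances(pool, cfg)
    metadata = generate_metadata(cfg)
    for pid in sequences:
        truth.neutral_flags.setdefault(pid, True)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(sequences, outdir / "plasmids.fasta")
        abund.abundance.to_csv(outdir / "abundance.tsv", sep="\t")
        abund.coverage.to_csv(outdir / "coverage.tsv", sep="\t")
        abund.read_depth.to_frame().to_csv(outdir / "read_depth.tsv", sep="\t")
        metadata.to_csv(outdir / "metadata.tsv", sep="\t")
        records.to_csv(outdir / "annotations.tsv", sep="\t")
        truth.to_json(outdir / "truth.json")
    return {"sequences": sequences, "records": records, "abundance": abund,
            "metadata": metadata, "truth": truth}
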