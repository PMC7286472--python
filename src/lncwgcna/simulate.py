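"""Synthetic data with planted ground truth for the whole pipeline.

The expression generator is a Gaussian factor model emulating a small
four-stage microarray design (default 7/6/6/3 samples from normal duct to
invasive lesion).  Each planted module m shares a latent factor

    f_m = beta_m * z(stage) + sqrt(1 - beta_m^2) * eta_m

and its member genes follow

    x_i = sqrt(rho_m) * f_m + sqrt(1 - rho_m) * eps_i

so the within-module gene-gene correlation is rho_m and the factor-trait
correlation is beta_m (population values).  Hub genes are planted with
*sample-exact* trait correlation (their noise is orthogonalized against the
realized stage score), mirroring the strong printed hub correlations this
kind of screen reports.  Background genes are pure noise.  Values sit on a
log2-intensity-like scale (baseline 8).

The probe-universe generator emits transcripts (lncRNA biotypes plus
protein-coding decoys), probe sets of 11 x 25-mers, and a truth map:
"clean" sets have >= 4 probes that are exact unique substrings of one
lncRNA; decoy classes are 1-mismatch probes, probes shared by two genes,
and sets with <= 3 matching probes.

The survival generator draws exponential event times with the hazard scaled
by ``hazard_ratio`` in the "high" group, under independent exponential
censoring calibrated to the requested censor fraction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reannotate import LNCRNA_BIOTYPES, TranscriptRecord

__all__ = [
    "STAGE_ORDER",
    "SimulationConfig",
    "ProbeUniverseConfig",
    "SyntheticTruth",
    "ExpressionDataset",
    "ProbeUniverse",
    "simulate_expression",
    "simulate_probe_universe",
    "probe_level_expression",
    "simulate_survival",
]

#: four sequential lesion stages, least to most advanced
STAGE_ORDER = ("normal", "IPMA", "IPMC", "invasive")

_BASELINE = 8.0  # log2-intensity-like location


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the expression simulation (defaults = training design)."""

    n_samples_per_stage: tuple[int, int, int, int] = (7, 6, 6, 3)
    module_sizes: tuple[int, ...] = (60, 50, 40)
    within_module_cor: tuple[float, ...] = (0.7, 0.7, 0.7)
    trait_effect: tuple[float, ...] = (-0.75, 0.0, 0.0)
    n_background_genes: int = 150
    n_hub_genes: int = 3
    hub_abs_cor: float = 0.9
    hub_module_mix: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_samples_per_stage) != 4 or any(
            n < 1 for n in self.n_samples_per_stage
        ):
            raise ValueError("n_samples_per_stage must be 4 positive counts")
        if len(self.module_sizes) != len(self.within_module_cor) or len(
            self.module_sizes
        ) != len(self.trait_effect):
            raise ValueError(
                "module_sizes, within_module_cor, trait_effect must align"
            )
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 1")
        if any(not 0 <= r < 1 for r in self.within_module_cor):
            raise ValueError("within_module_cor must lie in [0, 1)")
        if any(abs(b) > 1 for b in self.trait_effect):
            raise ValueError("|trait_effect| must be <= 1")
        if not 0 < self.hub_abs_cor < 1:
            raise ValueError("hub_abs_cor must lie in (0, 1)")
        if not 0 <= self.hub_module_mix <= 1:
            raise ValueError("hub_module_mix must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_hub_genes and max(
            (abs(b) for b in self.trait_effect), default=0
        ) == 0:
            raise ValueError("hub genes require a module with nonzero trait_effect")

    @property
    def n_samples(self) -> int:
        return sum(self.n_samples_per_stage)

    @property
    def n_genes(self) -> int:
        return sum(self.module_sizes) + self.n_hub_genes + self.n_background_genes


@dataclass
class SyntheticTruth:
    """Planted ground truth carried alongside every synthetic artifact."""

    module_labels: pd.Series  # gene -> int, 0 = background
    hub_genes: list[str] = field(default_factory=list)
    factor_trait_cor: dict[int, float] = field(default_factory=dict)
    probe_to_transcript: pd.Series | None = None  # probe -> transcript_id or ""
    clean_lncrna_genes: list[str] = field(default_factory=list)
    decoy_classes: dict[str, str] = field(default_factory=dict)  # probeset -> class


@dataclass
class ExpressionDataset:
    matrix: pd.DataFrame  # genes x samples
    stages: pd.Series  # sample -> stage label


def _stage_z(n_per_stage: tuple[int, ...]) -> tuple[pd.Series, np.ndarray]:
    samples, scores, labels = [], [], []
    for stage_idx, (name, n) in enumerate(zip(STAGE_ORDER, n_per_stage), start=1):
        for j in range(n):
            samples.append(f"{name}_{j + 1}")
            labels.append(name)
            scores.append(float(stage_idx))
    scores = np.asarray(scores)
    z = (scores - scores.mean()) / scores.std()
    stages = pd.Series(labels, index=samples, name="stage")
    return stages, z


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Draw one expression matrix and its planted truth (seed-deterministic)."""
    rng = np.random.default_rng(config.seed)
    stages, z = _stage_z(config.n_samples_per_stage)
    n = config.n_samples

    gene_ids, labels, rows = [], [], []
    factor_trait = {}
    hub_genes: list[str] = []

    factors: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for m, (size, rho, beta) in enumerate(
        zip(config.module_sizes, config.within_module_cor, config.trait_effect),
        start=1,
    ):
        eta = rng.standard_normal(n)
        f = beta * z + np.sqrt(1.0 - beta**2) * eta
        factors[m] = (f, eta)
        factor_trait[m] = float(beta)
        for j in range(size):
            eps = config.noise_sd * rng.standard_normal(n)
            rows.append(np.sqrt(rho) * f + np.sqrt(1.0 - rho) * eps)
            gene_ids.append(f"LNC{m:02d}{j + 1:04d}")
            labels.append(m)

    if config.n_hub_genes:
        hub_module = int(
            np.argmax([abs(b) for b in config.trait_effect]) + 1
        )
        sign = np.sign(config.trait_effect[hub_module - 1])
        r = config.hub_abs_cor
        w = config.hub_module_mix
        _, eta = factors[hub_module]
        for j in range(config.n_hub_genes):
            eps = rng.standard_normal(n)
            # a hub is a strongly connected *member* of its module, so its
            # non-trait component shares the module's latent factor noise;
            # orthogonalizing and standardizing that component makes the
            # *sample* correlation with the stage score exactly sign * r
            u = w * eta + np.sqrt(1.0 - w**2) * eps
            u = u - (u @ z) / (z @ z) * z
            u = (u - u.mean()) / u.std()
            x = sign * r * z + np.sqrt(1.0 - r**2) * u
            rows.append(x)
            gid = f"LNCHUB{j + 1:02d}"
            gene_ids.append(gid)
            labels.append(hub_module)
            hub_genes.append(gid)

    for j in range(config.n_background_genes):
        rows.append(config.noise_sd * rng.standard_normal(n))
        gene_ids.append(f"LNCBG{j + 1:04d}")
        labels.append(0)

    matrix = pd.DataFrame(
        _BASELINE + np.vstack(rows), index=gene_ids, columns=stages.index
    )
    matrix.index.name = "gene_id"
    truth = SyntheticTruth(
        module_labels=pd.Series(labels, index=gene_ids, name="module"),
        hub_genes=hub_genes,
        factor_trait_cor=factor_trait,
    )
    return ExpressionDataset(matrix=matrix, stages=stages), truth


# ---------------------------------------------------------------------------
# probe universe


@dataclass(frozen=True)
class ProbeUniverseConfig:
    """Stated world of the probe/transcript universe."""

    n_clean_lncrna: int = 40
    n_protein_coding: int = 8  # clean matches, wrong biotype
    n_mismatch_sets: int = 6
    n_multimap_sets: int = 6
    n_sparse_sets: int = 6  # <= 3 matching probes
    n_unprobed_transcripts: int = 130
    probes_per_set: int = 11
    n_matching_probes: int = 8  # matching probes in a clean set
    sparse_matching_probes: int = 3
    probe_length: int = 25
    transcript_length: tuple[int, int] = (300, 800)
    seed: int = 0
    clean_gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.transcript_length[0] < self.probe_length:
            raise ValueError("transcripts must be at least one probe long")
        if not 4 <= self.n_matching_probes <= self.probes_per_set:
            raise ValueError("clean sets need 4..probes_per_set matching probes")
        if self.sparse_matching_probes > 3:
            raise ValueError("sparse sets must have <= 3 matching probes")
        if self.clean_gene_ids is not None and len(self.clean_gene_ids) != self.n_clean_lncrna:
            raise ValueError("clean_gene_ids must have n_clean_lncrna entries")


@dataclass
class ProbeUniverse:
    transcripts: list[TranscriptRecord]
    attributes: pd.DataFrame  # transcript_id, gene_id, gene_symbol, biotype
    probes: pd.DataFrame  # probe_id, probeset_id, sequence


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _windows(rng: np.random.Generator, seq: str, k: int, count: int) -> list[tuple[int, str]]:
    """Distinct windows of length k sampled without replacement from seq."""
    offsets = rng.choice(len(seq) - k + 1, size=count, replace=False)
    return [(int(o), seq[o : o + k]) for o in offsets]


def simulate_probe_universe(
    config: ProbeUniverseConfig,
) -> tuple[ProbeUniverse, SyntheticTruth]:
    """Generate transcripts + probe sets with planted clean/decoy structure."""
    rng = np.random.default_rng(config.seed)
    k = config.probe_length
    lo, hi = config.transcript_length
    biotype_cycle = itertools.cycle(LNCRNA_BIOTYPES)

    transcripts: list[TranscriptRecord] = []
    probe_rows: list[dict] = []
    probe_truth: dict[str, str] = {}
    decoys: dict[str, str] = {}
    clean_genes: list[str] = []
    counter = itertools.count(1)

    def new_transcript(gene_id: str, symbol: str, biotype: str, seq: str | None = None) -> TranscriptRecord:
        tid = f"TX{next(counter):05d}.1"
        if seq is None:
            seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        rec = TranscriptRecord(tid, gene_id, symbol, biotype, seq)
        transcripts.append(rec)
        return rec

    def add_set(set_id: str, matching: list[tuple[str, int, str]], n_random: int) -> None:
        """matching: (transcript_id, offset, window); pad with random probes."""
        probe_no = itertools.count(1)
        for tid, off, window in matching:
            pid = f"{set_id}_p{next(probe_no)}"
            probe_rows.append(
                {"probe_id": pid, "probeset_id": set_id, "sequence": window}
            )
            probe_truth[pid] = tid
        for _ in range(n_random):
            pid = f"{set_id}_p{next(probe_no)}"
            probe_rows.append(
                {"probe_id": pid, "probeset_id": set_id, "sequence": _random_seq(rng, k)}
            )
            probe_truth[pid] = ""

    # clean lncRNA sets
    for i in range(config.n_clean_lncrna):
        gid = (
            config.clean_gene_ids[i]
            if config.clean_gene_ids is not None
            else f"LNCG{i + 1:04d}"
        )
        rec = new_transcript(gid, f"LNC-{i + 1}", next(biotype_cycle))
        wins = _windows(rng, rec.sequence, k, config.n_matching_probes)
        add_set(
            f"set_clean{i + 1:03d}",
            [(rec.transcript_id, o, w) for o, w in wins],
            config.probes_per_set - config.n_matching_probes,
        )
        clean_genes.append(gid)

    # protein-coding decoys: perfectly matched but not lncRNA
    for i in range(config.n_protein_coding):
        rec = new_transcript(f"PCG{i + 1:04d}", f"PC-{i + 1}", "protein_coding")
        wins = _windows(rng, rec.sequence, k, config.n_matching_probes)
        sid = f"set_pc{i + 1:03d}"
        add_set(
            sid,
            [(rec.transcript_id, o, w) for o, w in wins],
            config.probes_per_set - config.n_matching_probes,
        )
        decoys[sid] = "protein_coding"

    # 1-mismatch decoys: every probe differs from its source window by 1 nt
    for i in range(config.n_mismatch_sets):
        rec = new_transcript(f"LNCMM{i + 1:03d}", f"MM-{i + 1}", next(biotype_cycle))
        wins = _windows(rng, rec.sequence, k, config.probes_per_set)
        sid = f"set_mm{i + 1:03d}"
        probe_no = itertools.count(1)
        for off, window in wins:
            pos = k // 2
            old = window[pos]
            new = rng.choice([b for b in "ACGT" if b != old])
            mutated = window[:pos] + new + window[pos + 1 :]
            pid = f"{sid}_p{next(probe_no)}"
            probe_rows.append(
                {"probe_id": pid, "probeset_id": sid, "sequence": mutated}
            )
            probe_truth[pid] = ""
        decoys[sid] = "mismatch"

    # multi-mapping decoys: two genes share the probed region verbatim
    for i in range(config.n_multimap_sets):
        shared = _random_seq(rng, max(lo, 2 * k + 50))
        rec_a = new_transcript(
            f"LNCMA{i + 1:03d}", f"MA-{i + 1}", next(biotype_cycle),
            seq=shared + _random_seq(rng, 50),
        )
        rec_b = new_transcript(
            f"LNCMB{i + 1:03d}", f"MB-{i + 1}", next(biotype_cycle),
            seq=_random_seq(rng, 50) + shared,
        )
        wins = _windows(rng, shared, k, config.probes_per_set)
        sid = f"set_multi{i + 1:03d}"
        add_set(sid, [(rec_a.transcript_id, o, w) for o, w in wins], 0)
        decoys[sid] = "multi-map"
        del rec_b

    # sparse sets: too few matching probes
    for i in range(config.n_sparse_sets):
        rec = new_transcript(f"LNCSP{i + 1:03d}", f"SP-{i + 1}", next(biotype_cycle))
        wins = _windows(rng, rec.sequence, k, config.sparse_matching_probes)
        sid = f"set_sparse{i + 1:03d}"
        add_set(
            sid,
            [(rec.transcript_id, o, w) for o, w in wins],
            config.probes_per_set - config.sparse_matching_probes,
        )
        decoys[sid] = "sparse-probeset"

    # unprobed padding transcripts
    for i in range(config.n_unprobed_transcripts):
        biotype = "protein_coding" if i % 3 == 0 else next(biotype_cycle)
        new_transcript(f"PAD{i + 1:04d}", f"PAD-{i + 1}", biotype)

    attributes = pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "gene_symbol": t.gene_symbol,
                "biotype": t.biotype,
            }
            for t in transcripts
        ]
    )
    probes = pd.DataFrame(probe_rows)
    universe = ProbeUniverse(transcripts=transcripts, attributes=attributes, probes=probes)
    truth = SyntheticTruth(
        module_labels=pd.Series(dtype=int),
        probe_to_transcript=pd.Series(probe_truth, name="transcript_id"),
        clean_lncrna_genes=clean_genes,
        decoy_classes=decoys,
    )
    return universe, truth


def probe_level_expression(
    dataset: ExpressionDataset,
    universe: ProbeUniverse,
    universe_truth: SyntheticTruth,
    probe_noise_sd: float = 0.25,
    probe_offset_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Expand gene-level expression to the probe level.

    Probes whose truth transcript belongs to a gene present in the
    gene-level matrix inherit that gene's profile plus a per-probe affinity
    offset and i.i.d. measurement noise; all other probes are noise around
    the baseline.
    """
    rng = np.random.default_rng(seed)
    tx_to_gene = dict(
        zip(universe.attributes["transcript_id"], universe.attributes["gene_id"])
    )
    n = dataset.matrix.shape[1]
    rows, ids = [], []
    for pid, tid in universe_truth.probe_to_transcript.items():
        gene = tx_to_gene.get(tid)
        offset = probe_offset_sd * rng.standard_normal()
        noise = probe_noise_sd * rng.standard_normal(n)
        if gene is not None and gene in dataset.matrix.index:
            rows.append(dataset.matrix.loc[gene].to_numpy() + offset + noise)
        else:
            rows.append(_BASELINE + offset + rng.standard_normal(n))
        ids.append(pid)
    out = pd.DataFrame(rows, index=ids, columns=dataset.matrix.columns)
    out.index.name = "probe_id"
    return out


def simulate_survival(
    n_per_group: tuple[int, int],
    hazard_ratio: float,
    censor_rate: float = 0.0,
    seed: int = 0,
    base_hazard: float = 0.1,
) -> pd.DataFrame:
    """Two-group exponential survival table with independent censoring.

    The "high" group's event hazard is ``base_hazard * hazard_ratio``; the
    "low" group's is ``base_hazard``.  Censoring times are exponential with
    a rate chosen so that, at hazard_ratio = 1, a fraction ``censor_rate``
    of observations are censored.  Columns: sample, time, event, group.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for name, n, hazard in (
        ("low", n_per_group[0], base_hazard),
        ("high", n_per_group[1], base_hazard * hazard_ratio),
    ):
        event_t = rng.exponential(1.0 / hazard, size=n)
        if censor_rate > 0:
            censor_hazard = base_hazard * censor_rate / (1.0 - censor_rate)
            censor_t = rng.exponential(1.0 / censor_hazard, size=n)
        else:
            censor_t = np.full(n, np.inf)
        t = np.minimum(event_t, censor_t)
        d = (event_t <= censor_t).astype(int)
        for j in range(n):
            rows.append(
                {
                    "sample": f"{name}_{j + 1}",
                    "time": float(t[j]),
                    "event": int(d[j]),
                    "group": name,
                }
            )
    return pd.DataFrame(rows)
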