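"""Synthetic single-egg microarray datasets with known ground truth.

The generator emulates the structure the analysis assumes: ~24 eggs from 5
clutches (one mother each), a bimodal probe population — non-expressed probes
with low mean and low variance, expressed probes with higher mean and higher
egg-to-egg variance — mother-level expression offsets on a subset of
expressed genes (the planted "signature"), small egg-level noise, per-array
multiplicative scaling distortions (additive in log2), multiple probes per
gene with probe-specific affinities, and optionally a handful of probes that
ignore the array scale (the behaviour of natively polyadenylated
transcripts).  Every planted label is recorded in a :class:`SimTruth` so
recovery by the analysis modules can be scored exactly.

All randomness flows from a single seed: ``numpy.random.SeedSequence(seed)``
is spawned into independent child streams for gene assignment, intensities,
and sequence generation, so any one output is reproducible bit-for-bit from
the seed alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import ProbeMatrix
from .enrichment import Motif

__all__ = ["SimConfig", "SimTruth", "SimConfigError", "generate_dataset", "generate_utrs", "write_dataset"]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror the study design (5 clutches of 4-5 eggs, 24 eggs total)
    and a variance structure in which 88% of expressed genes stay within a
    twofold range inside clutches (egg_sd 0.24, see the methods note).
    All intensity parameters are log2 units.
    """

    n_genes: int = 1000
    probes_per_gene: int = 2
    expressed_fraction: float = 0.34
    n_mothers: int = 5
    eggs_per_clutch: tuple[int, ...] = (5, 5, 5, 4, 5)
    signature_fraction: float = 0.2
    level_separation: float = 2.0
    egg_sd: float = 0.24
    clutch_sd: float = 0.1
    bg_mean: float = 4.0
    bg_sd: float = 0.05
    expr_mean_range: tuple[float, float] = (6.0, 10.0)
    probe_affinity_sd: float = 0.25
    array_scale_sd: float = 0.1
    max_levels: int = 2
    n_suspect_probes: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.probes_per_gene < 1:
            raise SimConfigError("n_genes and probes_per_gene must be >= 1")
        for name in ("expressed_fraction", "signature_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise SimConfigError(f"{name} must lie in (0, 1)")
        if self.level_separation < 0:
            raise SimConfigError("level_separation must be >= 0")
        if len(self.eggs_per_clutch) != self.n_mothers:
            raise SimConfigError("eggs_per_clutch must have one entry per mother")
        if any(e < 1 for e in self.eggs_per_clutch):
            raise SimConfigError("every clutch needs at least one egg")
        if not 2 <= self.max_levels <= self.n_mothers:
            raise SimConfigError("max_levels must lie in [2, n_mothers]")
        if self.expr_mean_range[0] >= self.expr_mean_range[1]:
            raise SimConfigError("expr_mean_range must be an increasing interval")

    @property
    def n_samples(self) -> int:
        return int(sum(self.eggs_per_clutch))


@dataclass
class SimTruth:
    """Ground-truth labels planted by the generator."""

    expressed_genes: set[str]
    signature_genes: dict[str, str]  # gene -> profile code, 1 digit per mother
    array_scales: dict[str, float]  # sample -> log2 scale offset
    probe_affinity: dict[str, float]
    suspect_probes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "expressed_genes": sorted(self.expressed_genes),
            "signature_genes": self.signature_genes,
            "array_scales": self.array_scales,
            "probe_affinity": self.probe_affinity,
            "suspect_probes": self.suspect_probes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _draw_codes(rng: np.random.Generator, n: int, n_mothers: int, max_levels: int) -> list[str]:
    """Random profile codes: level assignments using 2..max_levels levels.

    A code must use more than one level (all-equal codes carry no signature)
    and its digits must cover 1..n_levels.
    """
    codes = []
    while len(codes) < n:
        n_levels = int(rng.integers(2, max_levels + 1))
        digits = rng.integers(1, n_levels + 1, size=n_mothers)
        if len(set(digits.tolist())) != n_levels:
            continue
        codes.append("".join(str(d) for d in digits))
    return codes


def generate_dataset(
    config: SimConfig,
) -> tuple[ProbeMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate a probe matrix, annotation, sample sheet, and ground truth.

    Expressed probe intensities are gene baseline + clutch offset + egg noise
    + probe affinity, plus the per-array log2 scale; non-expressed probes are
    background draws + probe affinity + scale.  Signature genes take their
    clutch offsets from a planted profile code (level 1 highest, consecutive
    levels ``level_separation`` apart, centered on the baseline); other
    expressed genes get small ``clutch_sd`` jitter.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_intensity = [np.random.default_rng(s) for s in ss.spawn(2)]

    n_g, ppg = config.n_genes, config.probes_per_gene
    genes = [f"g{i:06d}" for i in range(n_g)]
    chromosomes = rng_assign.integers(1, 26, size=n_g)

    probe_ids, transcript_ids, gene_of_probe = [], [], []
    for gi, g in enumerate(genes):
        for k in range(ppg):
            probe_ids.append(f"p_{g}_{k}")
            transcript_ids.append(f"t_{g}_{k}")
            gene_of_probe.append(gi)
    gene_of_probe = np.array(gene_of_probe)

    annotation = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "transcript_id": transcript_ids,
            "gene_id": [genes[i] for i in gene_of_probe],
            "chromosome": [f"chr{chromosomes[i]}" for i in gene_of_probe],
        }
    )

    samples, mothers = [], []
    for mi, n_eggs in enumerate(config.eggs_per_clutch, start=1):
        for e in range(1, n_eggs + 1):
            samples.append(f"M{mi}_e{e}")
            mothers.append(f"M{mi}")
    sheet = pd.DataFrame({"sample_id": samples, "mother_id": mothers})
    mother_index = np.array([int(m[1:]) - 1 for m in mothers])

    n_expressed = int(round(config.expressed_fraction * n_g))
    expressed_idx = rng_assign.choice(n_g, size=n_expressed, replace=False)
    expressed_mask_gene = np.zeros(n_g, dtype=bool)
    expressed_mask_gene[expressed_idx] = True

    n_sig = int(round(config.signature_fraction * n_expressed))
    sig_idx = rng_assign.choice(expressed_idx, size=n_sig, replace=False)
    codes = _draw_codes(rng_assign, n_sig, config.n_mothers, config.max_levels)
    code_of_gene = dict(zip(sig_idx.tolist(), codes))

    baselines = rng_intensity.uniform(*config.expr_mean_range, size=n_g)
    # per-gene per-mother offsets
    clutch_offset = rng_intensity.normal(0, config.clutch_sd, size=(n_g, config.n_mothers))
    for gi, code in code_of_gene.items():
        digits = np.array([int(d) for d in code], dtype=float)
        offsets = -(digits - digits.mean()) * config.level_separation
        clutch_offset[gi] = offsets  # level 1 sits highest

    n_probes = len(probe_ids)
    n_s = config.n_samples
    affinity = rng_intensity.normal(0, config.probe_affinity_sd, size=n_probes)
    scale = rng_intensity.normal(0, config.array_scale_sd, size=n_s)

    expressed_probe = expressed_mask_gene[gene_of_probe]
    values = np.empty((n_probes, n_s))
    bg = rng_intensity.normal(config.bg_mean, config.bg_sd, size=(n_probes, n_s))
    egg = rng_intensity.normal(0, config.egg_sd, size=(n_probes, n_s))
    signal = (
        baselines[gene_of_probe][:, None]
        + clutch_offset[gene_of_probe][:, mother_index]
        + egg
    )
    values = np.where(expressed_probe[:, None], signal, bg)
    values += affinity[:, None]

    suspect: list[str] = []
    scale_mask = np.ones(n_probes, dtype=bool)
    if config.n_suspect_probes:
        candidates = np.flatnonzero(expressed_probe)
        if len(candidates) < config.n_suspect_probes:
            raise SimConfigError("not enough expressed probes to plant suspects")
        pick = rng_assign.choice(candidates, size=config.n_suspect_probes, replace=False)
        scale_mask[pick] = False
        suspect = [probe_ids[i] for i in sorted(pick)]
    values = values + np.where(scale_mask[:, None], scale[None, :], 0.0)

    matrix = ProbeMatrix(
        pd.DataFrame(values, index=probe_ids, columns=samples),
        dict(zip(samples, mothers)),
    )
    truth = SimTruth(
        expressed_genes={genes[i] for i in expressed_idx},
        signature_genes={genes[i]: c for i, c in code_of_gene.items()},
        array_scales=dict(zip(samples, scale.tolist())),
        probe_affinity=dict(zip(probe_ids, affinity.tolist())),
        suspect_probes=suspect,
    )
    return matrix, annotation, sheet, truth


def generate_utrs(
    genes: list[str],
    planted: dict[str, set[str]],
    length: int = 300,
    seed: int = 0,
    motifs: list[Motif] | None = None,
) -> list[SeqRecord]:
    """Random-background 3'UTR sequences with planted motif occurrences.

    ``planted`` maps motif ids to the genes whose UTR must contain at least
    one exact occurrence of that motif's consensus, inserted at a random
    position.  Motif ids resolve against ``motifs`` (default: the builtin
    3'UTR element set).
    """
    from .enrichment import builtin_motifs

    if motifs is None:
        motifs = builtin_motifs()
    by_id = {m.id: m for m in motifs}
    gene_set = set(genes)
    for mid, targets in planted.items():
        if mid not in by_id:
            raise SimConfigError(f"unknown motif id {mid!r}")
        if not set(targets) <= gene_set:
            raise SimConfigError(f"planted genes for {mid!r} not all in gene list")
        if len(by_id[mid]) > length:
            raise SimConfigError(f"motif {mid!r} longer than UTR length {length}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    alphabet = np.array(list("ACGU"))
    to_plant: dict[str, list[Motif]] = {}
    for mid, targets in planted.items():
        for g in targets:
            to_plant.setdefault(g, []).append(by_id[mid])

    records = []
    for g in genes:
        seq = rng.choice(alphabet, size=length)
        for motif in to_plant.get(g, []):
            site = motif.consensus(rng)
            start = int(rng.integers(0, length - len(site) + 1))
            seq[start : start + len(site)] = list(site)
        records.append(SeqRecord(Seq("".join(seq)), id=g, description=""))
    return records


def write_dataset(out_dir, matrix: ProbeMatrix, annotation: pd.DataFrame, sheet: pd.DataFrame, truth: SimTruth) -> None:
    """Write the TSV/JSON bundle (matrix, annotation, sample sheet, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.values.rename_axis("probe_id").to_csv(out / "intensity_matrix.tsv", sep="\t")
    annotation.to_csv(out / "probe_annotation.tsv", sep="\t", index=False)
    sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
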