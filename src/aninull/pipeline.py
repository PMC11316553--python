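"""End-to-end orchestration: subsample -> assemble -> ANI -> null -> calls.

The study design, per strain: draw ``n_replicates`` seeded subsamples of
``n_pairs`` read pairs, build one assembly per replicate (the built-in
emulator by default; an external assembler can be plugged in as a command
template), and compute ANI for disjoint consecutive replicate pairs so no
assembly is reused.  Per species, the same-strain ANI values are pooled,
bootstrap-enlarged, ANOVA-checked and KDE-fitted into a
:class:`~aninull.nulldist.PooledNull`; observed genome pairs are then
projected onto their species' null and called identical / related /
different.  Everything is deterministic under ``master_seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shlex
import subprocess
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ani import symmetric_ani
from .formats import Assembly, PairedReadSet, read_fasta, write_fastq_pair
from .nulldist import PooledNull, StrainCall, StrainNullClassifier, classify_pair
from .simulate import AssemblyEmulationModel, Genome, emulate_assembly
from .subsample import derive_seeds, disjoint_pairs, make_replicates

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every numeric parameter of the analysis, with the study defaults."""

    n_pairs: int = 150_000
    n_replicates: int = 50
    bootstrap_B: int = 10_000
    k: int = 16
    fragment_len: int = 3_000
    min_contig_len: int = 1_000
    p_low: float = 0.05
    p_high: float = 0.95
    master_seed: int = 0
    species_map: dict[str, str] = field(default_factory=dict)
    assembly_backend: str = "emulator"  # or a command template
    emulation: AssemblyEmulationModel = field(default_factory=AssemblyEmulationModel)
    min_mapped: int = 10

    def __post_init__(self) -> None:
        if self.n_replicates % 2 != 0:
            raise ValueError("n_replicates must be even (disjoint pairing)")
        if not (0.0 <= self.p_low < self.p_high <= 1.0):
            raise ValueError("need 0 <= p_low < p_high <= 1")

    def ani_kwargs(self) -> dict:
        return dict(fragment_len=self.fragment_len, k=self.k,
                    min_mapped=self.min_mapped)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["emulation"] = dataclasses.asdict(self.emulation)
        return d


@dataclass
class StrainInput:
    """One strain's inputs: reads to subsample and, for the emulator
    backend, the genome the emulator rebuilds assemblies from."""

    label: str
    species: str
    reads: PairedReadSet
    genome: Genome | None = None


@dataclass
class StudyReport:
    """Per-species nulls plus per-pair strain calls and summary counts."""

    calls: list[StrainCall]
    nulls: dict[str, PooledNull]
    config: dict
    summary: dict[str, int] = field(default_factory=dict)
    seeds: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = {c: 0 for c in ("identical", "related", "different")}
            for call in self.calls:
                self.summary[call.category] += 1
        if sum(self.summary.values()) != len(self.calls):
            raise ValueError("summary counts must sum to the number of pairs")

    def to_json(self, path) -> None:
        payload = {
            "version": __version__,
            "config": self.config,
            "seeds": self.seeds,
            "summary": self.summary,
            "anova": {sp: (None if null.anova is None else vars(null.anova))
                      for sp, null in self.nulls.items()},
            "calls": [vars(c) for c in self.calls],
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2)


def _external_assembly(template: str, replicate: PairedReadSet,
                       label: str) -> Assembly:
    """Run an external assembler command template on one replicate.

    The template must contain {r1}, {r2} and {out} placeholders; {out}
    receives the expected FASTA path.  Contract only — never exercised by
    the test suite.
    """
    with tempfile.TemporaryDirectory() as tmp:
        r1 = Path(tmp) / "r1.fastq"
        r2 = Path(tmp) / "r2.fastq"
        out = Path(tmp) / "assembly.fasta"
        write_fastq_pair(replicate, r1, r2)
        cmd = template.format(r1=r1, r2=r2, out=out)
        subprocess.run(shlex.split(cmd), check=True)
        return read_fasta(out, label=label)


def replicate_assemblies(strain: StrainInput, config: PipelineConfig,
                         strain_seed: int) -> tuple[list[Assembly], list[int]]:
    """Subsample one strain's reads into replicates and build one assembly
    per replicate (same replicate seed drives subsample and emulation)."""
    reps = make_replicates(strain.reads, config.n_replicates, config.n_pairs,
                           master_seed=strain_seed)
    assemblies = []
    for i, (replicate, seed) in enumerate(zip(reps.replicates, reps.seeds)):
        label = f"{strain.label}_rep{i:02d}"
        if config.assembly_backend == "emulator":
            if strain.genome is None:
                raise ValueError(
                    f"strain {strain.label!r}: the emulator backend needs the "
                    f"strain genome")
            model = dataclasses.replace(config.emulation,
                                        min_contig_len=config.min_contig_len)
            assemblies.append(emulate_assembly(strain.genome, model,
                                               seed=seed, label=label))
        else:
            assemblies.append(_external_assembly(config.assembly_backend,
                                                 replicate, label))
    return assemblies, reps.seeds


def run_null_construction(config: PipelineConfig, strains: list[StrainInput]
                          ) -> tuple[dict[str, PooledNull], dict[str, list[int]]]:
    """Build the per-species same-strain ANI null distributions.

    Returns the nulls plus the per-strain replicate seeds used.  Strains
    with too few reads are skipped with an error record; a species with a
    single strain still gets a null, with the ANOVA flagged undefined.
    """
    strain_seeds = derive_seeds(config.master_seed, len(strains) + 1)
    boot_seed = strain_seeds[-1]
    per_species: dict[str, dict[str, list[float]]] = {}
    seeds_used: dict[str, list[int]] = {}
    for strain, sseed in zip(strains, strain_seeds):
        t0 = time.perf_counter()
        try:
            assemblies, rep_seeds = replicate_assemblies(strain, config, sseed)
        except Exception as exc:
            logger.error("strain %r skipped: %s", strain.label, exc)
            continue
        seeds_used[strain.label] = rep_seeds
        values = []
        for a, b in disjoint_pairs(assemblies):
            ani = symmetric_ani(a, b, **config.ani_kwargs())
            if ani is None:
                logger.warning("undefined ANI for replicate pair of %r",
                               strain.label)
                continue
            values.append(ani)
        per_species.setdefault(strain.species, {})[strain.label] = values
        logger.info("strain %s: %d same-strain ANI values in %.1fs",
                    strain.label, len(values), time.perf_counter() - t0)

    nulls: dict[str, PooledNull] = {}
    for species, per_strain in per_species.items():
        per_strain = {k: v for k, v in per_strain.items() if v}
        if not per_strain:
            logger.error("species %r: no usable same-strain ANI values", species)
            continue
        values = np.concatenate([np.asarray(v) for v in per_strain.values()])
        labels = np.concatenate([[s] * len(v) for s, v in per_strain.items()])
        clf = StrainNullClassifier(n_bootstrap=config.bootstrap_B,
                                   p_low=config.p_low, p_high=config.p_high,
                                   random_state=boot_seed)
        clf.fit(values, labels)
        nulls[species] = clf.to_pooled_null(species)
    return nulls, seeds_used


@dataclass
class ObservedPair:
    """One genome pair to classify; ``ani`` may be precomputed (external
    table) or left None to be computed by the built-in estimator."""

    species: str
    assembly_a: Assembly | None = None
    assembly_b: Assembly | None = None
    label_a: str = ""
    label_b: str = ""
    ani: float | None = None


def run_classification(config: PipelineConfig,
                       nulls: dict[str, PooledNull],
                       observed_pairs: list[ObservedPair],
                       seeds: dict[str, list[int]] | None = None) -> StudyReport:
    """Project observed genome-pair ANIs onto their species' null and call
    each pair identical / related / different."""
    classifiers: dict[str, StrainNullClassifier] = {}
    for species, null in nulls.items():
        clf = StrainNullClassifier(n_bootstrap=config.bootstrap_B,
                                   p_low=config.p_low, p_high=config.p_high)
        clf.fit(null.ani_values, null.strain_labels)
        if null.bootstrap_sample is not None:
            clf.bootstrap_sample_ = np.asarray(null.bootstrap_sample)
            clf._sorted_bootstrap_ = np.sort(clf.bootstrap_sample_)
        clf.anova_ = null.anova
        classifiers[species] = clf

    calls: list[StrainCall] = []
    for pair in observed_pairs:
        if pair.species not in classifiers:
            raise ValueError(f"no null distribution for species {pair.species!r}")
        clf = classifiers[pair.species]
        if pair.ani is None:
            ani = symmetric_ani(pair.assembly_a, pair.assembly_b,
                                **config.ani_kwargs())
            if ani is None:
                logger.warning("pair (%s, %s): ANI undefined, skipped",
                               pair.label_a or pair.assembly_a.label,
                               pair.label_b or pair.assembly_b.label)
                continue
        else:
            ani = pair.ani
        p = float(clf.predict_p([ani])[0])
        category = classify_pair(p, config.p_low, config.p_high)
        calls.append(StrainCall(
            genome_a=pair.label_a or (pair.assembly_a.label if pair.assembly_a
                                      else "?"),
            genome_b=pair.label_b or (pair.assembly_b.label if pair.assembly_b
                                      else "?"),
            observed_ani=float(ani), empirical_p=p, category=category))
    return StudyReport(calls=calls, nulls=nulls, config=config.to_dict(),
                       seeds=seeds or {})
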