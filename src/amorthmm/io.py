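"""Plain-text file formats and run configuration.

On-disk conventions follow community pore-model files: the emission table
is a TSV of ``kmer, level_mean, level_stdv`` (standard deviation on disk,
variance in memory — conversion happens here and only here), with an
optional ``provenance`` column. Events, labels and calls are TSV/BED-like
text. All writers emit rows in a deterministic order (lexicographic
k-mer, ascending position) and format floats with ``repr`` (shortest
round-trip representation).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .emission_amortizer import AmortizerConfig
from .eval_harness import METHODS, ExperimentConfig
from .hmm_caller import EmissionTable, GaussianParams, SiteCall
from .kmer_core import validate_kmer


class PoreModelParseError(ValueError):
    """A pore-model TSV violated the format; message carries the line number."""


def _fmt(x: float) -> str:
    return repr(float(x))


def write_pore_model(
    table: EmissionTable, path: str | Path, provenance: bool = True
) -> None:
    """Write an emission table in the pore-model TSV dialect."""
    lines = ["\t".join(["kmer", "level_mean", "level_stdv"] + (["provenance"] if provenance else []))]
    for kmer in table.kmers():
        p = table.params(kmer)
        row = [kmer, _fmt(p.mu), _fmt(math.sqrt(p.var))]
        if provenance:
            row.append(table.provenance(kmer))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pore_model(path: str | Path) -> EmissionTable:
    """Read a pore-model TSV into an emission table (variance = stdv^2).

    A ``provenance`` column is honoured when present, defaulting to
    ``learned``. Raises :class:`PoreModelParseError` with the offending
    line number on duplicate k-mers, non-positive stdv or bad symbols.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise PoreModelParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    try:
        i_kmer = header.index("kmer")
        i_mean = header.index("level_mean")
        i_stdv = header.index("level_stdv")
    except ValueError as e:
        raise PoreModelParseError(f"{path}:1: bad header {header}") from e
    i_prov = header.index("provenance") if "provenance" in header else None
    table = EmissionTable()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            kmer = validate_kmer(parts[i_kmer], k=len(parts[i_kmer]))
            mean = float(parts[i_mean])
            stdv = float(parts[i_stdv])
        except (ValueError, IndexError) as e:
            raise PoreModelParseError(f"{path}:{ln}: {e}") from e
        if stdv <= 0:
            raise PoreModelParseError(f"{path}:{ln}: non-positive stdv {stdv}")
        if kmer in table:
            raise PoreModelParseError(f"{path}:{ln}: duplicate k-mer {kmer}")
        prov = parts[i_prov] if i_prov is not None and len(parts) > i_prov else "learned"
        table.set(kmer, GaussianParams(mean, stdv**2), prov)
    return table


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write an aligned event table (read_id, position, kmer, current)."""
    df = events[["read_id", "position", "kmer", "current"]].sort_values(
        ["read_id", "position"], kind="stable"
    )
    with open(path, "w") as fh:
        fh.write("read_id\tposition\tkmer\tcurrent\n")
        for r, p, s, c in df.itertuples(index=False):
            fh.write(f"{r}\t{p}\t{s}\t{_fmt(c)}\n")


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": int, "position": int})
    df["kmer"] = df["kmer"].astype("category")
    return df


def write_labels_bed(labels: pd.DataFrame, path: str | Path, chrom: str = "ref") -> None:
    """Site labels as BED-like text: chrom, start, end (CG dinucleotide), state, coverage."""
    df = labels.sort_values("position")
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fh.write(
                f"{chrom}\t{int(row['position'])}\t{int(row['position']) + 2}"
                f"\t{row['state']}\t{int(row['coverage'])}\n"
            )


def read_labels_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, state, cov = line.split("\t")
        rows.append({"position": int(start), "coverage": int(cov), "state": state})
    return pd.DataFrame(rows)


def write_calls(
    calls: Iterable[SiteCall], path: str | Path, dialect: str = "tsv", chrom: str = "ref"
) -> None:
    """Write site calls as TSV (position, llr, call, coverage) or BED.

    The BED dialect uses 0-based half-open intervals of length 2 covering
    the CG dinucleotide; the TSV dialect prints llr to 6 decimal places.
    """
    calls = sorted(calls, key=lambda c: c.position)
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("position\tllr\tcall\tcoverage\n")
            for c in calls:
                state = "methylated" if c.call else "unmethylated"
                fh.write(f"{c.position}\t{c.llr:.6f}\t{state}\t{c.coverage}\n")
        elif dialect == "bed":
            for c in calls:
                state = "methylated" if c.call else "unmethylated"
                fh.write(
                    f"{chrom}\t{c.position}\t{c.position + 2}\t{state}\t{_fmt(c.llr)}\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def write_frequency_bed(calls: Iterable[SiteCall], path: str | Path, chrom: str = "ref") -> None:
    """Per-site methylated fraction as BED-like text."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: c.position):
            fh.write(
                f"{chrom}\t{c.position}\t{c.position + 2}"
                f"\t{_fmt(c.methylated_fraction)}\t{c.coverage}\n"
            )


def write_kmer_list(kmers: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in sorted(kmers)))


def read_kmer_list(path: str | Path) -> set[str]:
    out = set()
    for line in Path(path).read_text().splitlines():
        s = line.strip().upper()
        if s:
            out.add(validate_kmer(s, k=len(s)))
    return out


def read_windows_tsv(path: str | Path) -> list[tuple[str, float]]:
    """(11-mer, count) pairs for panel selection; header optional."""
    out = []
    for line in Path(path).read_text().splitlines():
        parts = line.split("\t")
        if not line.strip() or parts[0].lower() in ("window", "kmer", "11mer"):
            continue
        out.append((parts[0].strip().upper(), float(parts[1]) if len(parts) > 1 else 1.0))
    return out


# --- run configuration ----------------------------------------------------


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulatorBlock(_Block):
    reference_length: int = 42_000
    cpg_density: float = 0.05
    methylated_fraction: float = 0.5
    n_window_types: int | None = 600
    head_fraction: float = 0.05
    head_share: float = 0.45
    stratify_methylation: bool = True
    n_reads: int = 3_150
    read_length: int = 400
    additive_effect_scale: float = 4.0
    pairwise_effect_scale: float = 0.4
    residual_scale: float = 0.5
    methylation_shift_scale: float = 2.5
    noise_var_range: tuple[float, float] = (1.0, 4.0)
    label_error_rate: float = 0.0
    min_label_coverage: int = 5


class HmmBlock(_Block):
    min_events: int = 2
    balance_training: bool = False
    normalize_size: bool = False
    p_stay: float = 0.0
    p_skip: float = 0.0


class AmortizerBlock(_Block):
    d: int = 3
    h: int = 32
    learning_rate: float = 1e-2
    epochs: int = 1500
    validation_fraction: float = 0.2


class EvalBlock(_Block):
    p_grid: tuple[float, ...] = (5.0, 10.0, 30.0, 100.0)
    n_folds: int = 6
    methods: tuple[str, ...] = METHODS
    novelty_threshold: float | None = None


class RunConfig(_Block):
    """Validated experiment configuration (unknown keys rejected)."""

    seeds: tuple[int, ...] = (0,)
    simulator: SimulatorBlock = Field(default_factory=SimulatorBlock)
    hmm: HmmBlock = Field(default_factory=HmmBlock)
    amortizer: AmortizerBlock = Field(default_factory=AmortizerBlock)
    eval: EvalBlock = Field(default_factory=EvalBlock)

    def to_experiment_config(self) -> ExperimentConfig:
        sim, ev = self.simulator, self.eval
        return ExperimentConfig(
            p_grid=ev.p_grid,
            n_folds=ev.n_folds,
            seeds=self.seeds,
            reference_length=sim.reference_length,
            cpg_density=sim.cpg_density,
            methylated_fraction=sim.methylated_fraction,
            n_window_types=sim.n_window_types,
            head_fraction=sim.head_fraction,
            head_share=sim.head_share,
            stratify_methylation=sim.stratify_methylation,
            n_reads=sim.n_reads,
            read_length=sim.read_length,
            additive_effect_scale=sim.additive_effect_scale,
            pairwise_effect_scale=sim.pairwise_effect_scale,
            residual_scale=sim.residual_scale,
            methylation_shift_scale=sim.methylation_shift_scale,
            noise_var_range=sim.noise_var_range,
            label_error_rate=sim.label_error_rate,
            min_label_coverage=sim.min_label_coverage,
            min_events=self.hmm.min_events,
            balance_training=self.hmm.balance_training,
            normalize_size=self.hmm.normalize_size,
            amortizer=AmortizerConfig(
                d=self.amortizer.d,
                h=self.amortizer.h,
                learning_rate=self.amortizer.learning_rate,
                epochs=self.amortizer.epochs,
                validation_fraction=self.amortizer.validation_fraction,
            ),
            methods=ev.methods,
            novelty_threshold=ev.novelty_threshold,
        )


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)
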