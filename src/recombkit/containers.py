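"""Core in-memory containers shared across the pipeline.

Genotype calls are held as a dense ``int8`` matrix with the field's usual
dose coding: 0 and 2 for the two homozygotes, 1 for heterozygotes and -1 for
missing.  Marker metadata travels as a pandas DataFrame ("panel") with
columns ``marker``, ``chrom``, ``pos`` sorted by chromosome and position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)


class RecombkitError(Exception):
    """Base class for package errors."""


class ConfigurationError(RecombkitError):
    pass


class DesignError(RecombkitError):
    pass


class ValidationError(RecombkitError):
    pass


@dataclass(frozen=True)
class Chromosome:
    """A chromosome of the physical map."""

    name: str
    length_bp: int
    centromere_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ConfigurationError(f"chromosome {self.name} has non-positive length")
        if not (0 < self.centromere_bp < self.length_bp):
            raise ConfigurationError(
                f"centromere of {self.name} outside (0, {self.length_bp})"
            )


def make_panel(chromosomes: Sequence[Chromosome], positions: dict[str, np.ndarray]) -> pd.DataFrame:
    """Assemble a marker panel DataFrame from per-chromosome positions."""
    frames = []
    for chrom in chromosomes:
        pos = np.asarray(positions[chrom.name], dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ConfigurationError(f"marker positions on {chrom.name} not strictly increasing")
        frames.append(
            pd.DataFrame(
                {
                    "marker": [f"{chrom.name}_{p}" for p in pos],
                    "chrom": chrom.name,
                    "pos": pos,
                }
            )
        )
    panel = pd.concat(frames, ignore_index=True)
    return panel


@dataclass
class FounderSet:
    """Fully homozygous founder inbreds on a common marker panel."""

    parents: list[str]
    chromosomes: list[Chromosome]
    panel: pd.DataFrame  # marker, chrom, pos
    haplotypes: np.ndarray  # (n_parents, n_markers) int8, values 0 or 2

    def __post_init__(self) -> None:
        if self.haplotypes.shape != (len(self.parents), len(self.panel)):
            raise ConfigurationError("haplotype matrix does not match parents x panel")
        if not np.isin(self.haplotypes, [0, 2]).all():
            raise ConfigurationError("founders must be fully homozygous (codes 0/2)")

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    def chrom_index(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.panel["chrom"].to_numpy() == name)

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class Cross:
    parent_i: str
    parent_j: str
    pop_id: str
    n_rils: int

    def __post_init__(self) -> None:
        if self.parent_i == self.parent_j:
            raise DesignError(f"cross {self.pop_id} mates a parent with itself")
        if self.n_rils < 1:
            raise DesignError(f"cross {self.pop_id} has no RILs")


@dataclass
class CrossDesign:
    """The crossing design: which parents found which RIL population."""

    crosses: list[Cross]

    def __post_init__(self) -> None:
        ids = [c.pop_id for c in self.crosses]
        if len(set(ids)) != len(ids):
            raise DesignError("population ids are not unique")

    @property
    def pop_ids(self) -> list[str]:
        return [c.pop_id for c in self.crosses]

    @property
    def parents(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.crosses:
            seen.setdefault(c.parent_i)
            seen.setdefault(c.parent_j)
        return list(seen)

    def cross(self, pop_id: str) -> Cross:
        for c in self.crosses:
            if c.pop_id == pop_id:
                return c
        raise KeyError(pop_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parent_i": [c.parent_i for c in self.crosses],
                "parent_j": [c.parent_j for c in self.crosses],
                "pop_id": [c.pop_id for c in self.crosses],
                "n_rils": [c.n_rils for c in self.crosses],
            }
        )


@dataclass
class GenotypeTable:
    """Individuals x markers genotype calls with per-marker quality scores.

    ``coding`` records whether calls are allele doses ("allele") or
    population-local parental-origin codes ("origin", 0 = homozygous for the
    parent_i allele).
    """

    individuals: list[str]
    populations: list[str]  # population id per individual
    panel: pd.DataFrame
    calls: np.ndarray  # (n_ind, n_markers) int8 in {-1, 0, 1, 2}
    quality: np.ndarray  # (n_markers,) float in [0, 1]
    coding: str = "allele"

    def __post_init__(self) -> None:
        n_ind, n_mark = self.calls.shape
        if n_ind != len(self.individuals) or n_ind != len(self.populations):
            raise ValidationError("call matrix rows do not match individuals")
        if n_mark != len(self.panel) or n_mark != len(self.quality):
            raise ValidationError("call matrix columns do not match panel")
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ValidationError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.panel)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset(self, ind_idx: np.ndarray | None = None, marker_idx: np.ndarray | None = None) -> "GenotypeTable":
        ind_idx = np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx)
        marker_idx = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeTable(
            individuals=[self.individuals[i] for i in ind_idx],
            populations=[self.populations[i] for i in ind_idx],
            panel=self.panel.iloc[marker_idx].reset_index(drop=True),
            calls=self.calls[np.ix_(ind_idx, marker_idx)].copy(),
            quality=self.quality[marker_idx].copy(),
            coding=self.coding,
        )

    def copy(self) -> "GenotypeTable":
        return replace(
            self,
            individuals=list(self.individuals),
            populations=list(self.populations),
            panel=self.panel.copy(),
            calls=self.calls.copy(),
            quality=self.quality.copy(),
        )


@dataclass
class WindowRates:
    """Population x window recombination rates (cM/Mbp) on a fixed grid.

    ``windows`` has columns chrom, start, end, width_bp, eff_width_bp; rows of
    ``rates`` follow ``pop_ids`` order and columns follow ``windows`` order.
    """

    pop_ids: list[str]
    windows: pd.DataFrame
    rates: np.ndarray  # (n_pop, n_windows) float, NaN allowed

    def __post_init__(self) -> None:
        if self.rates.shape != (len(self.pop_ids), len(self.windows)):
            raise ValidationError("rates matrix does not match pops x windows")

    @property
    def chrom_names(self) -> list[str]:
        return list(dict.fromkeys(self.windows["chrom"]))

    def chromosome_means(self) -> pd.DataFrame:
        """Per-population arithmetic mean of each chromosome's window rates."""
        out = {}
        chroms = self.windows["chrom"].to_numpy()
        for chrom in self.chrom_names:
            cols = chroms == chrom
            with np.errstate(invalid="ignore"):
                out[chrom] = np.nanmean(self.rates[:, cols], axis=1)
        return pd.DataFrame(out, index=self.pop_ids)

    def genome_means(self) -> pd.Series:
        """Unweighted mean of the chromosome means, one value per population."""
        cm = self.chromosome_means()
        return cm.mean(axis=1)

    def consensus_window_rates(self) -> np.ndarray:
        """Cross-population mean rate per window (NaN-skipping)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.rates, axis=0)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for p, pop in enumerate(self.pop_ids):
            for w in range(len(self.windows)):
                recs.append(
                    (
                        self.windows["chrom"].iat[w],
                        int(self.windows["start"].iat[w]),
                        int(self.windows["end"].iat[w]),
                        pop,
                        self.rates[p, w],
                    )
                )
        return pd.DataFrame(recs, columns=["chrom", "start", "end", "pop_id", "rate"])


@dataclass
class TrueRecombinationModel:
    """Simulator ground truth: baseline landscape plus log-scale cross effects.

    The per-cross landscape is ``L_ij(w) = L0(w) * exp(g_i + g_j + s_ij)``:
    effects act multiplicatively so rates stay non-negative, while the
    analysis-side decomposition stays additive on the rate scale.
    """

    chromosomes: list[Chromosome]
    window_bp: int
    baseline: dict[str, np.ndarray]  # chrom -> per-window base rate, cM/Mbp
    gre: dict[str, float]  # parent -> g_i (log scale)
    sre: dict[str, float]  # pop_id -> s_ij (log scale)
    tau2_g: float
    tau2_s: float

    def window_edges(self, chrom: Chromosome) -> np.ndarray:
        n_win = len(self.baseline[chrom.name])
        edges = np.minimum(np.arange(n_win + 1) * self.window_bp, chrom.length_bp)
        return edges.astype(float)

    def cross_multiplier(self, cross: Cross) -> float:
        return float(
            np.exp(self.gre[cross.parent_i] + self.gre[cross.parent_j] + self.sre[cross.pop_id])
        )

    def cross_landscape(self, cross: Cross, chrom_name: str) -> np.ndarray:
        return self.baseline[chrom_name] * self.cross_multiplier(cross)

    def genetic_length_morgans(self, cross: Cross, chrom: Chromosome) -> float:
        """Genetic length in Morgans: sum of window rate x width / 100."""
        edges = self.window_edges(chrom)
        widths_mbp = np.diff(edges) / 1e6
        return float(np.sum(self.cross_landscape(cross, chrom.name) * widths_mbp) / 100.0)

    def total_effect(self, cross: Cross) -> float:
        """g_i + g_j + s_ij, the log-scale deviation of a cross."""
        return self.gre[cross.parent_i] + self.gre[cross.parent_j] + self.sre[cross.pop_id]
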