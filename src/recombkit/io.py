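"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (one file per population, GT field, contig headers
from the chromosome spec; written/read through pysam) or as a plain CSV
matrix (individuals x markers).  The design table is TSV, ground truth is
YAML, window rates are BED-like TSV and fit results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .containers import Chromosome, Cross, CrossDesign, GenotypeTable, WindowRates
from .qcmap import CleanReport, LinkageMap
from .remodel import GREFit

_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}


def write_vcf(geno: GenotypeTable, chromosomes: list[Chromosome], path: str | Path) -> None:
    """Write a population's calls as an uncompressed VCF with GT fields."""
    header = pysam.VariantHeader()
    for chrom in chromosomes:
        header.contigs.add(chrom.name, length=chrom.length_bp)
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    for ind in geno.individuals:
        header.add_sample(ind)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for m in range(geno.n_markers):
            rec = vf.new_record(
                contig=str(geno.panel["chrom"].iat[m]),
                start=int(geno.panel["pos"].iat[m]),
                stop=int(geno.panel["pos"].iat[m]) + 1,
                alleles=("A", "T"),
                id=str(geno.panel["marker"].iat[m]),
            )
            for s, ind in enumerate(geno.individuals):
                rec.samples[ind]["GT"] = _GT[int(geno.calls[s, m])]
            vf.write(rec)


def read_vcf(path: str | Path, pop_id: str = "pop") -> GenotypeTable:
    """Read a VCF written by :func:`write_vcf` back into a GenotypeTable."""
    markers, chroms, poss, rows = [], [], [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            markers.append(rec.id)
            chroms.append(rec.contig)
            poss.append(rec.start)
            calls = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                calls.append(-1 if gt is None or gt[0] is None else int(sum(gt)))
            rows.append(calls)
    panel = pd.DataFrame({"marker": markers, "chrom": chroms, "pos": poss})
    calls = np.asarray(rows, dtype=np.int8).T
    return GenotypeTable(
        individuals=samples,
        populations=[pop_id] * len(samples),
        panel=panel,
        calls=calls,
        quality=np.ones(len(panel)),
    )


def write_genotype_csv(geno: GenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame(geno.calls, index=geno.individuals, columns=geno.panel["marker"])
    df.insert(0, "population", geno.populations)
    df.to_csv(path)


def read_genotype_csv(path: str | Path, panel: pd.DataFrame,
                      quality: np.ndarray | None = None) -> GenotypeTable:
    df = pd.read_csv(path, index_col=0)
    pops = df.pop("population").tolist()
    df = df[panel["marker"]]
    return GenotypeTable(
        individuals=[str(i) for i in df.index],
        populations=[str(p) for p in pops],
        panel=panel.reset_index(drop=True),
        calls=df.to_numpy(dtype=np.int8),
        quality=np.ones(len(panel)) if quality is None else quality,
    )


def write_design(design: CrossDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> CrossDesign:
    df = pd.read_csv(path, sep="\t")
    return CrossDesign(crosses=[
        Cross(str(r.parent_i), str(r.parent_j), str(r.pop_id), int(r.n_rils))
        for r in df.itertuples()
    ])


def write_truth(truth, path: str | Path) -> None:
    doc = {
        "window_bp": truth.window_bp,
        "tau2_g": truth.tau2_g,
        "tau2_s": truth.tau2_s,
        "chromosomes": [
            {"name": c.name, "length_bp": c.length_bp, "centromere_bp": c.centromere_bp}
            for c in truth.chromosomes
        ],
        "baseline": {k: [float(x) for x in v] for k, v in truth.baseline.items()},
        "gre": truth.gre,
        "sre": truth.sre,
    }
    Path(path).write_text(yaml.safe_dump(doc))


def write_window_rates(wr: WindowRates, path: str | Path) -> None:
    """BED-like TSV: chrom, start, end, pop_id, rate."""
    wr.to_frame().to_csv(path, sep="\t", index=False)


def read_window_rates(path: str | Path) -> WindowRates:
    df = pd.read_csv(path, sep="\t")
    pops = list(dict.fromkeys(df["pop_id"]))
    first = df[df["pop_id"] == pops[0]]
    windows = first[["chrom", "start", "end"]].reset_index(drop=True)
    windows["width_bp"] = windows["end"] - windows["start"]
    windows["eff_width_bp"] = windows["width_bp"]
    rates = np.vstack([
        df[df["pop_id"] == p]["rate"].to_numpy() for p in pops
    ])
    return WindowRates(pop_ids=pops, windows=windows, rates=rates)


def write_linkage_map(linkmap: LinkageMap, path: str | Path) -> None:
    linkmap.to_frame().to_csv(path, sep="\t", index=False)


def write_clean_report(report: CleanReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def write_fit(fit: GREFit, path: str | Path) -> None:
    doc = {
        "mode": fit.mode,
        "intercept": fit.intercept,
        "fixed_effects": [float(b) for b in fit.mu],
        "variance_components": {
            "sigma2_a": fit.vc.sigma2_a,
            "sigma2_d": fit.vc.sigma2_d,
            "sigma2_e": fit.vc.sigma2_e,
            "confounded": fit.vc.confounded,
        },
        "h2": fit.h2,
        "u_gre": {k: float(v) for k, v in fit.u_gre.items()},
        "u_sre": {k: float(v) for k, v in fit.u_sre.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=2))
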