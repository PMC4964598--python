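"""Seeded synthetic data with the statistical structure the method assumes.

One generator produces a coherent bundle: a small random genome, stranded
gene models, per-sample pileups whose promoter depth decays with distance
upstream of the TSS, and two cohorts of per-individual VCFs with planted
core-promoter variants under a configured sharing profile, Ts:Tv
composition and indel fraction.  Truth tables list every plant so each
pipeline stage can be scored exactly.

Depth is generated directly as pileup columns rather than reads: the
method operates on mapped coverage, and read simulation would add nothing
testable.  A single RNG stream drives the whole bundle in documented order
(genome, gene strands, coverage samples, group A plan, group B plan), so a
fixed seed gives byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import PileupColumn, write_pileup
from .genome import GeneModel, PromoterWindow, build_windows, to_genomic, rel_length
from .variants import PromoterVariant, VcfRecord

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSION_PARTNERS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}

__all__ = ["SimConfig", "SimBundle", "simulate", "truth_eval",
           "default_sharing_profile", "read_config"]


@dataclass
class SimConfig:
    """Generator settings; defaults are the study conditions the method
    targets, scaled to a desk-size genome.

    The cohort has 27 individuals per group, indels are 28% of plants, the
    Ts:Tv plant target is 1.5 (so the doubled ratio 2xTs/Tv is 3.0), and
    pileup depth peaks at the downstream window end and decays upstream at
    0.004 per base.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 80_000
    n_genes: int = 100
    strand_fraction: float = 0.5
    rel_lo: int = -500
    rel_hi: int = 100
    core_lo: int = -100
    core_hi: int = 100
    # coverage model
    n_coverage_samples: int = 3
    lambda_max: float = 20.0
    decay: float = 0.004
    # cohort plan
    groups: tuple[str, str] = ("groupA", "groupB")
    n_individuals: int = 27
    n_variants_per_group: int = 1000
    sharing_profile: tuple[int, ...] | None = None
    cross_group_overlap: float = 0.1
    ts_tv_target: float = 1.5
    indel_fraction: float = 0.28
    depth_low: int = 5
    depth_high: int = 30
    n_low_depth: int = 0   # plants whose carriers all get depth 1..3
    min_depth_rule: int = 4

    def __post_init__(self) -> None:
        if self.n_genes % self.n_chroms:
            raise ValueError("n_genes must divide evenly over n_chroms")
        for name in ("lambda_max", "decay", "cross_group_overlap",
                     "ts_tv_target", "indel_fraction", "strand_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sharing_profile is not None:
            prof = tuple(int(x) for x in self.sharing_profile)
            if len(prof) != self.n_individuals:
                raise ValueError("sharing_profile must have one count per level 1..N")
            if any(x < 0 for x in prof):
                raise ValueError("sharing_profile counts must be >= 0")
            if sum(prof) != self.n_variants_per_group:
                raise ValueError(
                    "sharing profile must sum to the planned variant total "
                    f"({sum(prof)} != {self.n_variants_per_group})"
                )
            self.sharing_profile = prof

    def profile(self) -> tuple[int, ...]:
        if self.sharing_profile is not None:
            return self.sharing_profile
        return default_sharing_profile(self.n_variants_per_group,
                                       self.n_individuals)


def default_sharing_profile(total: int, n: int) -> tuple[int, ...]:
    """A monotone-decreasing profile with counts proportional to 1/k.

    Mimics the observed cohort shape: most variants private to one
    individual, a long thin tail of widely shared ones.  Deterministic
    rounding makes the counts sum exactly to *total*.
    """
    weights = np.array([1.0 / k for k in range(1, n + 1)])
    raw = weights / weights.sum() * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return tuple(int(c) for c in counts)


@dataclass
class SimBundle:
    """Everything one simulate() call produced, in memory plus file paths."""

    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    windows: list[PromoterWindow]
    coverage_pileups: list[list[PileupColumn]]
    cohorts: dict[str, dict[str, list[VcfRecord]]]
    truth: pd.DataFrame
    profiles: dict[str, tuple[int, ...]]
    paths: dict[str, object] = field(default_factory=dict)


def _make_genome(rng: np.random.Generator, cfg: SimConfig) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(
            bases[rng.integers(0, 4, size=cfg.chrom_length)]
        )
        for i in range(cfg.n_chroms)
    }


def _make_genes(rng: np.random.Generator, cfg: SimConfig) -> list[GeneModel]:
    per_chrom = cfg.n_genes // cfg.n_chroms
    margin = max(-cfg.rel_lo, cfg.rel_hi) + 100
    usable = cfg.chrom_length - 2 * margin
    spacing = usable // per_chrom
    span = rel_length(cfg.rel_lo, cfg.rel_hi)
    if spacing < span + 1:
        raise ValueError("chromosome too short for non-overlapping windows")
    genes: list[GeneModel] = []
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        for g in range(per_chrom):
            tss = margin + g * spacing + spacing // 2
            strand = "+" if rng.random() < cfg.strand_fraction else "-"
            genes.append(GeneModel(f"gene{c + 1:02d}_{g + 1:04d}", chrom,
                                   strand, tss))
    return genes


def _coverage_sample(
    rng: np.random.Generator,
    cfg: SimConfig,
    genome: Mapping[str, str],
    windows: Sequence[PromoterWindow],
) -> list[PileupColumn]:
    """Poisson depth per window position; mean decays upstream of rel_hi."""
    cols: list[PileupColumn] = []
    rels = [r for r in range(cfg.rel_lo, cfg.rel_hi + 1) if r != 0]
    dists = np.array([rel_length(r, cfg.rel_hi) - 1 for r in rels])
    means = cfg.lambda_max * np.exp(-cfg.decay * dists)
    for w in windows:
        if not w.primary:
            continue
        depths = rng.poisson(means)
        for r, d in zip(rels, depths):
            if d == 0:
                continue
            gpos = to_genomic(w, r)
            ref = genome[w.chrom][gpos - 1]
            cols.append(PileupColumn(w.chrom, gpos, int(d), {ref: int(d)}))
    cols.sort(key=lambda c: (c.chrom, c.pos))
    return cols


def _candidate_sites(
    cfg: SimConfig, windows: Sequence[PromoterWindow]
) -> list[tuple[str, int, str, int]]:
    """All (chrom, gpos, gene_id, rel) core-window sites of primary windows."""
    sites = []
    for w in windows:
        if not w.primary:
            continue
        for r in range(cfg.core_lo, cfg.core_hi + 1):
            if r == 0:
                continue
            sites.append((w.chrom, to_genomic(w, r), w.gene_id, r))
    return sites


def _plant_alleles(
    rng: np.random.Generator,
    cfg: SimConfig,
    genome: Mapping[str, str],
    site: tuple[str, int, str, int],
) -> tuple[str, str, str]:
    """Choose (ref, alt, vclass) at a site honouring Ts:Tv and indel plan."""
    chrom, gpos, _gene, _rel = site
    seq = genome[chrom]
    ref_base = seq[gpos - 1]
    if rng.random() < cfg.indel_fraction:
        length = int(rng.integers(2, 11))
        if rng.random() < 0.5 and gpos + length <= len(seq):  # deletion
            return seq[gpos - 1: gpos + length - 1], ref_base, "indel"
        ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length - 1)])
        return ref_base, ref_base + ins, "indel"
    p_ts = cfg.ts_tv_target / (cfg.ts_tv_target + 1.0)
    if rng.random() < p_ts:
        return ref_base, TRANSITION_PARTNER[ref_base], "SNP"
    alt = TRANSVERSION_PARTNERS[ref_base][int(rng.integers(0, 2))]
    return ref_base, alt, "SNP"


def _plan_group(
    rng: np.random.Generator,
    cfg: SimConfig,
    genome: Mapping[str, str],
    group: str,
    sites: list,
    reuse: list[tuple] | None,
) -> list[dict]:
    """Plan one group's variants: site, alleles, sharing level, carriers, depths.

    *sites* is mutated (consumed) so successive groups use disjoint fresh
    sites; *reuse* supplies (site, ref, alt, vclass) tuples shared verbatim
    from the other group.
    """
    profile = cfg.profile()
    levels = [k for k, c in enumerate(profile, start=1) for _ in range(c)]
    total = len(levels)
    n_reuse = len(reuse) if reuse else 0
    if total - n_reuse > len(sites):
        raise ValueError("not enough distinct core-window sites for the plan")
    individuals = [f"{group}_ind{j + 1:02d}" for j in range(cfg.n_individuals)]
    rng.shuffle(levels)
    plans: list[dict] = []
    for i in range(total):
        if reuse and i < n_reuse:
            site, ref, alt, vclass = reuse[i]
        else:
            site = sites.pop()
            ref, alt, vclass = _plant_alleles(rng, cfg, genome, site)
        low = len(plans) < cfg.n_low_depth
        k = levels[i]
        carriers = [individuals[j]
                    for j in rng.choice(cfg.n_individuals, size=k, replace=False)]
        if low:
            depths = rng.integers(1, cfg.min_depth_rule, size=k)
        else:
            depths = rng.integers(cfg.depth_low, cfg.depth_high + 1, size=k)
        plans.append({
            "group": group, "site": site, "ref": ref, "alt": alt,
            "vclass": vclass, "level": k, "low_depth": low,
            "carriers": carriers, "depths": [int(d) for d in depths],
        })
    return plans


def simulate(config: SimConfig, out_dir: str | None = None) -> SimBundle:
    """Generate the full bundle; write files under *out_dir* when given.

    Files: genome.fa, genes.bed, coverage_<i>.pileup.tsv per sample,
    <group>/<individual>.vcf per cohort member, truth_variants.tsv and
    truth_sharing.tsv.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genome = _make_genome(rng, cfg)
    genes = _make_genes(rng, cfg)
    windows = build_windows(genes, cfg.rel_lo, cfg.rel_hi,
                            cfg.core_lo, cfg.core_hi)
    pileups = [
        _coverage_sample(rng, cfg, genome, windows)
        for _ in range(cfg.n_coverage_samples)
    ]

    sites = _candidate_sites(cfg, windows)
    rng.shuffle(sites)
    sites = [tuple(s) for s in sites]
    group_a, group_b = cfg.groups
    plans_a = _plan_group(rng, cfg, genome, group_a, sites, reuse=None)
    n_overlap = int(round(cfg.cross_group_overlap * cfg.n_variants_per_group))
    reuse_pool = [p for p in plans_a if not p["low_depth"]]
    reuse_idx = rng.choice(len(reuse_pool), size=min(n_overlap, len(reuse_pool)),
                           replace=False)
    reuse = [
        (reuse_pool[i]["site"], reuse_pool[i]["ref"], reuse_pool[i]["alt"],
         reuse_pool[i]["vclass"])
        for i in sorted(int(i) for i in reuse_idx)
    ]
    plans_b = _plan_group(rng, cfg, genome, group_b, sites, reuse=reuse)

    cohorts: dict[str, dict[str, list[VcfRecord]]] = {}
    rows = []
    for group, plans in ((group_a, plans_a), (group_b, plans_b)):
        inds = {f"{group}_ind{j + 1:02d}": [] for j in range(cfg.n_individuals)}
        for p in plans:
            chrom, gpos, gene_id, rel = p["site"]
            for ind, depth in zip(p["carriers"], p["depths"]):
                inds[ind].append(VcfRecord(chrom, gpos, p["ref"], p["alt"], depth))
                rows.append({
                    "group": group, "individual": ind, "chrom": chrom,
                    "pos": gpos, "ref": p["ref"], "alt": p["alt"],
                    "gene_id": gene_id, "rel": rel, "depth": depth,
                    "vclass": p["vclass"], "level": p["level"],
                    "low_depth": p["low_depth"],
                })
        for ind in inds:
            inds[ind].sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
        cohorts[group] = inds
    truth = pd.DataFrame(rows)
    profiles = {g: cfg.profile() for g in cfg.groups}

    paths: dict[str, object] = {}
    if out_dir is not None:
        paths = _write_bundle(out_dir, cfg, genome, genes, windows,
                              pileups, cohorts, truth, profiles)
    return SimBundle(cfg, genome, genes, windows, pileups, cohorts,
                     truth, profiles, paths)


def _write_bundle(out_dir, cfg, genome, genes, windows, pileups,
                  cohorts, truth, profiles) -> dict:
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, object] = {}
    fasta = os.path.join(out_dir, "genome.fa")
    with open(fasta, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")
    paths["genome"] = fasta

    bed = os.path.join(out_dir, "genes.bed")
    with open(bed, "w") as fh:
        for g in genes:
            # BED6: TSS is start (0-based) on +, end on -
            if g.strand == "+":
                start, end = g.tss - 1, g.tss + 999
            else:
                start, end = max(0, g.tss - 1000), g.tss
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")
    paths["annotation"] = bed

    paths["pileups"] = []
    for i, cols in enumerate(pileups, start=1):
        p = os.path.join(out_dir, f"coverage_{i}.pileup.tsv")
        write_pileup(cols, p)
        paths["pileups"].append(p)

    contig_lines = "".join(
        f"##contig=<ID={c},length={len(s)}>\n" for c, s in genome.items()
    )
    paths["vcfs"] = {}
    for group, inds in cohorts.items():
        gdir = os.path.join(out_dir, group)
        os.makedirs(gdir, exist_ok=True)
        paths["vcfs"][group] = {}
        for ind, records in inds.items():
            vp = os.path.join(gdir, f"{ind}.vcf")
            with open(vp, "w") as fh:
                fh.write("##fileformat=VCFv4.2\n")
                fh.write(contig_lines)
                fh.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                         'Description="Site depth">\n')
                fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
                for r in records:
                    fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t"
                             f"PASS\tDP={r.depth}\n")
            paths["vcfs"][group][ind] = vp

    tpath = os.path.join(out_dir, "truth_variants.tsv")
    truth.to_csv(tpath, sep="\t", index=False)
    paths["truth"] = tpath
    spath = os.path.join(out_dir, "truth_sharing.tsv")
    with open(spath, "w") as fh:
        fh.write("group\tlevel\tcount\n")
        for group, prof in profiles.items():
            for k, c in enumerate(prof, start=1):
                fh.write(f"{group}\t{k}\t{c}\n")
    paths["sharing"] = spath
    return paths


def truth_eval(
    mined: Iterable,
    truth_keys: Iterable[tuple[str, int, str, str]],
) -> dict[str, float]:
    """Recall and precision of mined variant keys against planted truth."""
    mined_keys = set()
    for m in mined:
        mined_keys.add(m.key if isinstance(m, (PromoterVariant, VcfRecord))
                       else tuple(m))
    truth_set = {tuple(k) for k in truth_keys}
    hit = len(mined_keys & truth_set)
    return {
        "n_truth": len(truth_set),
        "n_mined": len(mined_keys),
        "n_hit": hit,
        "recall": hit / len(truth_set) if truth_set else 1.0,
        "precision": hit / len(mined_keys) if mined_keys else 1.0,
    }


def read_config(path: str) -> SimConfig:
    """Read a SimConfig from a flat key = value file.

    Integers, floats, and comma-separated integer lists (for
    sharing_profile) are parsed by field type; unknown keys are rejected.
    """
    import dataclasses

    fields = {f.name: f for f in dataclasses.fields(SimConfig)}
    kwargs: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            if key in ("sharing_profile", "groups"):
                parts = [p.strip() for p in val.split(",")]
                kwargs[key] = tuple(
                    int(p) if key == "sharing_profile" else p for p in parts
                )
            elif key in ("lambda_max", "decay", "cross_group_overlap",
                         "ts_tv_target", "indel_fraction", "strand_fraction"):
                kwargs[key] = float(val)
            else:
                kwargs[key] = int(val)
    return SimConfig(**kwargs)
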