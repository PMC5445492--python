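"""End-to-end orchestration: detect -> classify -> cluster/curate ->
annotate -> mask/abundance -> phylogeny.

Each genome is processed independently (detection through abundance); the
phylogenetic stage then places the family consensus RT/RNaseH domains of
all genomes on one NJ tree, rooted on a Gypsy outgroup, and applies the
two-criterion clade rule.  Every numeric threshold lives in
:class:`PipelineConfig`; stage code never hard-codes one.  A per-stage
structured log records input/output counts at each filter so every summary
number can be audited from the emitted artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import abundance as ab
from . import annotate as an
from . import classify as cl
from . import detect as dt
from . import families as fam
from . import io as cio
from . import phylo as ph

logger = logging.getLogger("copiascan")


@dataclass
class PipelineConfig:
    """Every tunable of the workflow, serializable to/from YAML."""

    genomes: dict = field(default_factory=dict)   # name -> FASTA path
    outdir: str = "copiascan_out"
    seed: int = 0
    # detection window
    ltr_min: int = 100
    ltr_max: int = 1000
    dist_min: int = 3000
    dist_max: int = 11000
    min_ltr_identity: float = 80.0
    # classification
    min_domain_bits: float = cl.DEFAULT_MIN_BITS
    clade_gap: float = cl.DEFAULT_CLADE_GAP
    # clustering / curation
    pass1_identity: float = fam.PASS1_IDENTITY
    pass1_coverage: float = fam.PASS1_COVERAGE
    pass2_identity: float = fam.PASS2_IDENTITY
    pass2_coverage: float = fam.PASS2_COVERAGE
    family_identity: float = fam.FAMILY_IDENTITY
    curation_max_insertion: int = fam.CURATION_MAX_INSERTION
    # masking / abundance
    mask_divergence: float = ab.MAX_DIVERGENCE
    size_filter: int = ab.SIZE_FILTER
    merge_gap: int = ab.MERGE_GAP
    # phylogeny
    model: str = "JTT"
    gamma_shape: float = 1.0
    bootstrap_replicates: int = 100
    min_support: float = 70.0
    min_species: int = 2

    def detector_params(self) -> dt.DetectorParams:
        return dt.DetectorParams(self.ltr_min, self.ltr_max, self.dist_min,
                                 self.dist_max, self.min_ltr_identity)

    def to_yaml(self, path) -> None:
        cio.write_config(asdict(self), path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = cio.read_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


def _stage(genome: str, name: str, n_in: int, n_out: int) -> None:
    logger.info("[%s] %s: %d -> %d", genome, name, n_in, n_out)


def process_genome(name: str, contigs: dict[str, str],
                   config: PipelineConfig, panel: cl.ReferencePanel) -> dict:
    """Run detection through abundance for one genome; returns all per-stage
    products keyed by stage name."""
    out: dict = {"genome": name, "contigs": contigs}
    params = config.detector_params()
    cands = dt.find_ltr_pairs(contigs, params)
    _stage(name, "detect", sum(map(len, contigs.values())), len(cands))
    refined = [dt.refine_boundaries(c, contigs) for c in cands]
    for c in refined:
        dt.detect_tsd(c, contigs)
    out["candidates"] = refined

    # classification ------------------------------------------------------
    elements: dict[str, str] = {}
    clades: dict[str, str] = {}
    superfamilies: dict[str, str] = {}
    for i, c in enumerate(refined):
        eid = f"{name}.e{i + 1:03d}"
        seq = contigs[c.contig][c.element_start:c.element_end]
        elements[eid] = seq
        dom = cl.extract_rt_rnaseh(seq, panel, config.min_domain_bits)
        if dom is None:
            superfamilies[eid] = "unknown"
            clades[eid] = "unassigned"
            continue
        superfamilies[eid] = cl.assign_superfamily(dom.protein, panel,
                                                   config.min_domain_bits)
        if superfamilies[eid] == "Copia":
            clades[eid] = cl.assign_clade(dom.protein, panel, eid,
                                          config.clade_gap).clade
        else:
            clades[eid] = "unassigned"
    copia = {e: s for e, s in elements.items() if superfamilies[e] == "Copia"}
    _stage(name, "classify-copia", len(elements), len(copia))
    out["elements"], out["superfamilies"], out["clades"] = \
        elements, superfamilies, clades

    # families -------------------------------------------------------------
    families, orphans = [], []
    if copia:
        clusters, leftovers = fam.cluster_pass1(copia, config.pass1_identity,
                                                config.pass1_coverage)
        clusters, orphans = fam.rescue_pass2(clusters, leftovers, copia,
                                             config.pass2_identity,
                                             config.pass2_coverage)
        families, more_orphans = fam.validate_families(
            clusters, copia, clades, singletons=[], threshold=config.family_identity)
        orphans = sorted(orphans + more_orphans)
        # singleton GalEa rescue: leftovers that are lone GalEa copies
        galea_singles = [o for o in orphans if clades.get(o) == "GalEa"]
        if galea_singles and not any(f.clade == "GalEa" for f in families):
            promoted, orphans = fam.validate_families(
                [], copia, clades, singletons=galea_singles,
                threshold=config.family_identity)
            for f in promoted:
                f.family_id = f"F{len(families) + 1:03d}"
                families.append(f)
    _stage(name, "families", len(copia), len(families))
    out["families"], out["orphans"] = families, orphans

    # orphan clade rescue ---------------------------------------------------
    protein_db = {}
    for f in families:
        dom = cl.extract_rt_rnaseh(f.consensus, panel, config.min_domain_bits)
        if dom is not None:
            protein_db[f.family_id] = (f.clade, dom.protein)
    orphan_calls = fam.assign_orphans(
        {o: elements[o] for o in orphans}, protein_db,
        translator=lambda dna: cl.rip_aware_translate(dna, panel))
    out["orphan_calls"] = orphan_calls

    # annotation ------------------------------------------------------------
    rows = []
    for i, c in enumerate(refined):
        eid = f"{name}.e{i + 1:03d}"
        row = an.annotate_element(eid, elements[eid], c.ltr_len, c.tsd)
        row["superfamily"] = superfamilies[eid]
        row["clade"] = clades[eid]
        rows.append(row)
    out["annotation"] = pd.DataFrame(rows)

    # masking / abundance ---------------------------------------------------
    genome_len = sum(len(s) for s in contigs.values())
    library = [(f.family_id, f.clade, f.consensus) for f in families]
    hits = ab.mask_genome(contigs, library, config.mask_divergence,
                          merge_gap=config.merge_gap) if library else []
    _stage(name, "mask", len(library), len(hits))
    detector_clades = [clades[e] for e in elements
                       if clades[e] not in ("unassigned",)]
    table = ab.abundance_table(name, genome_len, detector_clades, hits,
                               config.size_filter)
    out["mask_hits"], out["abundance"] = hits, table
    return out


def run_pipeline(config: PipelineConfig,
                 genomes: dict[str, dict[str, str]] | None = None) -> dict:
    """Execute the full workflow.

    ``genomes`` may be passed in memory; otherwise ``config.genomes`` paths
    are read.  Artifacts are written under ``config.outdir``.  Returns
    {"per_genome": ..., "summary": DataFrame, "tree": ..., "clades": ...}.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if genomes is None:
        genomes = {n: cio.read_fasta(p) for n, p in config.genomes.items()}
    panel = cl.default_panel()
    results = {}
    for name in sorted(genomes):
        try:
            results[name] = process_genome(name, genomes[name], config, panel)
        except Exception as exc:  # noqa: BLE001 - stage failures must name the stage
            raise RuntimeError(f"pipeline failed for genome {name!r}: {exc}") from exc
        _write_genome_artifacts(results[name], outdir)

    # cross-genome phylogeny ------------------------------------------------
    msa, species = {}, {}
    for name, res in results.items():
        for f in res["families"]:
            dom = cl.extract_rt_rnaseh(f.consensus, panel)
            if dom is not None:
                leaf = f"{name}.{f.family_id}"
                msa[leaf] = dom.protein
                species[leaf] = name
    tree = clade_calls = None
    if len(msa) >= 3:
        out_ref = next(e for e in panel.entries if e.superfamily == "Gypsy")
        msa["OUTGROUP"] = out_ref.sequence
        species["OUTGROUP"] = "outgroup"
        aligned = fam._mafft(msa)
        tree, supports = ph.bootstrap_support(
            aligned, config.bootstrap_replicates, seed=config.seed,
            gamma_shape=config.gamma_shape)
        clade_calls = ph.call_clades(tree, supports, species, "OUTGROUP",
                                     config.min_support, config.min_species)
        cio.write_newick(tree, outdir / "families.nwk")
        pd.DataFrame([{"clade_id": c.clade_id,
                       "members": ",".join(c.members),
                       "species": ",".join(c.species),
                       "support": c.support} for c in clade_calls]).to_csv(
            outdir / "clades.tsv", sep="\t", index=False)

    summary = _summary_frame(results)
    cio.write_tsv(summary, outdir / "summary.tsv")
    comparison = None
    if len(results) >= 3:
        comparison = ab.compare_estimators([r["abundance"]
                                            for r in results.values()])
    return {"per_genome": results, "summary": summary, "tree": tree,
            "clades": clade_calls, "estimator_comparison": comparison}


def _summary_frame(results: dict) -> pd.DataFrame:
    rows = []
    for name, res in sorted(results.items()):
        t = res["abundance"]
        row = {"genome": name,
               "candidates": len(res["candidates"]),
               "copia_elements": sum(1 for s in res["superfamilies"].values()
                                     if s == "Copia"),
               "families": len(res["families"]),
               "orphans": len(res["orphans"])}
        for clade in ("GalEa", "FunCo1", "OtherCopia"):
            row[f"{clade}_detector"] = t.detector_copies.get(clade, 0)
            row[f"{clade}_mask_ge3kb"] = t.mask_copies_ge3kb.get(clade, 0)
            row[f"{clade}_pct"] = round(t.proportions.get(clade, 0.0), 2)
        for est, r in t.ratios.items():
            row[f"ratio_{est}"] = r
        rows.append(row)
    return pd.DataFrame(rows)


def _write_genome_artifacts(res: dict, outdir: Path) -> None:
    name = res["genome"]
    gdir = outdir / name
    gdir.mkdir(parents=True, exist_ok=True)
    feats = []
    for i, c in enumerate(res["candidates"]):
        eid = f"{name}.e{i + 1:03d}"
        attrs = {"ID": eid, "ltr_identity": c.ltr_identity,
                 "clade": res["clades"][eid]}
        feats.append(cio.GFF3Feature(c.contig, "copiascan", "LTR_retrotransposon",
                                     c.element_start, c.element_end,
                                     str(c.ltr_identity), c.strand, attrs))
        for span, part in ((c.ltr5_span, "five_prime_LTR"),
                           (c.ltr3_span, "three_prime_LTR")):
            feats.append(cio.GFF3Feature(c.contig, "copiascan", part,
                                         span[0], span[1], ".", c.strand,
                                         {"Parent": eid}))
        if c.tsd:
            feats.append(cio.GFF3Feature(c.contig, "copiascan",
                                         "target_site_duplication",
                                         c.element_start - len(c.tsd),
                                         c.element_start, ".", c.strand,
                                         {"Parent": eid, "seq": c.tsd}))
    cio.write_gff3(feats, gdir / "elements.gff3")
    if res["elements"]:
        cio.write_fasta(res["elements"], gdir / "elements.fa")
    if res["families"]:
        cio.write_fasta({f"{f.family_id} clade={f.clade} n={len(f.members)}":
                         f.consensus for f in res["families"]},
                        gdir / "consensi.fa")
        member_rows = [{"family_id": f.family_id, "member": m,
                        "clade": f.clade,
                        "singleton": f.is_orphan_singleton}
                       for f in res["families"] for m in f.members]
        cio.write_tsv(pd.DataFrame(member_rows), gdir / "families.tsv")
    cio.write_tsv(res["annotation"], gdir / "annotation.tsv")
    mask_rows = [{"contig": h.contig, "start": h.start, "end": h.end,
                  "family_id": h.family_id, "clade": h.clade,
                  "divergence": h.divergence, "strand": h.strand}
                 for h in res["mask_hits"]]
    cio.write_tsv(pd.DataFrame(mask_rows,
                               columns=["contig", "start", "end", "family_id",
                                        "clade", "divergence", "strand"]),
                  gdir / "mask_hits.tsv")
    cio.write_tsv(res["abundance"].to_frame(), gdir / "abundance.tsv")
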