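"""End-to-end orchestration of the plasmid-prophage detection pipeline.

Stage order: genome deduplication -> marker-family clustering -> MSA ->
profile building (or loading shipped profiles) -> size filter -> marker
screen -> all-vs-all -> BBH -> COGtriangles -> pangenome -> network export
-> grouping -> feature extraction -> classification -> reports.  Every stage
writes its artifact under the output directory; reruns with an identical
config are byte-identical because all randomness flows from the single
config seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import classify as clf
from . import cluster as clu
from . import grouping, hmm, orthology, synth
from . import io as pio
from . import msa as msa_mod
from .align import nucleotide_scheme, protein_scheme
from .records import PlasmidRecord, ProteinRecord
from .screen import ScreenConfig, ScreenResult, screen_genomes, size_filter

log = logging.getLogger("plasphage")


@dataclass
class PipelineConfig:
    seed: int = 0
    out: str = "plasphage_out"
    # either a synthetic generator block or explicit input paths
    synthetic: Optional[dict] = None
    genomes: Optional[str] = None
    proteins: Optional[str] = None
    gff: Optional[str] = None
    families_dir: Optional[str] = None
    profiles_dir: Optional[str] = None  # pre-built profiles; skips MSA stage
    screen: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    calibrate: bool = False
    decoys: int = 500
    shift_to_terminase: bool = False

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass
class PipelineResult:
    outdir: Path
    config: PipelineConfig
    dataset: Optional[synth.SyntheticDataset]
    dedup_clusters: list
    representatives: list[str]
    size_filtered: list[str]
    profiles: list[hmm.ProfileHMM]
    screen_result: ScreenResult
    ortholog_clusters: list
    pangenome: Optional[orthology.PangenomeMatrix]
    groups: list
    calls: list[clf.ProphageCall]
    calls_table: "object"
    counts_table: "object"


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.synthetic is not None:
        spec_kwargs = dict(cfg.synthetic)
        spec_kwargs.setdefault("seed", cfg.seed)
        if "state_mix" in spec_kwargs:
            spec_kwargs["state_mix"] = {str(k): int(v) for k, v in
                                        spec_kwargs["state_mix"].items()}
        if "genome_length_range" in spec_kwargs:
            spec_kwargs["genome_length_range"] = tuple(
                spec_kwargs["genome_length_range"])
        spec = synth.GeneratorSpec(**spec_kwargs)
        dataset = synth.generate(spec)
        input_dir = outdir / "00_input"
        dataset.write(input_dir)
        return dataset, dataset.genomes, dataset.proteins, input_dir / "families"
    if cfg.genomes is None:
        raise ValueError("config must provide either 'synthetic' or 'genomes'")
    genomes = pio.read_genomes_fasta(cfg.genomes)
    genome_seqs = {g.id: g.sequence for g in genomes}
    if cfg.proteins:
        plist = pio.read_proteins_fasta(cfg.proteins)
    elif cfg.gff:
        plist = pio.read_gff3(cfg.gff, genome_seqs)
    else:
        from .screen import orf_scan
        plist = [p for g in genomes for p in orf_scan(g)]
    proteins: dict[str, list[ProteinRecord]] = {g.id: [] for g in genomes}
    for p in plist:
        if p.genome_id not in proteins:
            raise ValueError(f"protein {p.id} references unknown genome {p.genome_id}")
        proteins[p.genome_id].append(p)
    families_dir = Path(cfg.families_dir) if cfg.families_dir else None
    return None, genomes, proteins, families_dir


def build_profiles_from_families(families_dir: Path, screen_cfg: ScreenConfig,
                                 calibrate: bool = False, decoys: int = 500,
                                 seed: int = 0) -> list[hmm.ProfileHMM]:
    """Cluster each family FASTA, align the biggest cluster, build a profile."""
    params = clu.ClusterParams(min_identity=screen_cfg.family_min_identity,
                               min_coverage=screen_cfg.family_min_coverage,
                               mode="local")
    scheme = protein_scheme()
    profiles = []
    for fasta in sorted(Path(families_dir).glob("*.faa")):
        name = fasta.stem
        members = pio.read_fasta(fasta)
        clusters = clu.greedy_cluster(members, params, scheme=scheme)
        big = clu.select_family_clusters(clusters, screen_cfg.family_min_size)
        if not big:
            log.warning("family %s: no cluster of >= %d members; skipped",
                        name, screen_cfg.family_min_size)
            continue
        largest = max(big, key=lambda c: len(c.member_ids))
        aln = msa_mod.center_star_msa(
            {mid: members[mid] for mid in largest.member_ids}, scheme)
        profile = hmm.build_profile(aln, name)
        if calibrate:
            profile = hmm.calibrate_evalues(profile, decoys=decoys,
                                            seed=(seed * 1009 + len(profiles)) % (2**31))
        profiles.append(profile)
        log.info("profile %s: %d members, M=%d", name,
                 len(largest.member_ids), profile.M)
    return profiles


def rotate_to_marker(genome: PlasmidRecord, proteins: list[ProteinRecord],
                     marker: str = "terminase"):
    """Rotate a circular genome so the given marker gene starts the sequence.

    Reporting-time convenience only; returns inputs unchanged when the
    genome is linear or lacks the marker.
    """
    anchors = [p for p in proteins if p.marker == marker]
    if not genome.circular or not anchors:
        return genome, proteins
    origin = min(a.start for a in anchors)  # 1-based
    n = genome.length_bp
    seq = genome.sequence[origin - 1:] + genome.sequence[:origin - 1]
    moved = []
    for p in proteins:
        shift = -(origin - 1)
        start = (p.start - 1 + shift) % n + 1
        end = start + (p.end - p.start)
        moved.append(dataclasses.replace(p, start=start, end=end))
    return PlasmidRecord(id=genome.id, sequence=seq, circular=True,
                         organism=genome.organism), moved


def run_pipeline(config) -> PipelineResult:
    """Run every stage; ``config`` is a PipelineConfig, dict, or YAML path."""
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.load(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig(**config)
    else:
        cfg = config
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)

    screen_cfg = ScreenConfig(**cfg.screen)
    feature_cfg = clf.FeatureConfig(**cfg.features)

    dataset, genomes, proteins, families_dir = _load_inputs(cfg, outdir)
    log.info("input: %d genomes, %d proteins", len(genomes),
             sum(len(v) for v in proteins.values()))

    # -- dedup --------------------------------------------------------------
    dedup_dir = outdir / "01_dedup"
    dedup_dir.mkdir(exist_ok=True)
    dedup_params = clu.ClusterParams(min_identity=screen_cfg.dedup_min_identity,
                                     min_coverage=screen_cfg.dedup_min_coverage,
                                     mode="global")
    genome_seqs = {g.id: g.sequence for g in genomes}
    dedup_clusters = clu.greedy_cluster(genome_seqs, dedup_params,
                                        scheme=nucleotide_scheme())
    clu.write_cluster_tsv(dedup_clusters, dedup_dir / "clusters.tsv")
    representatives = sorted(c.representative_id for c in dedup_clusters)
    (dedup_dir / "representatives.txt").write_text(
        "".join(r + "\n" for r in representatives))
    log.info("dedup: %d genomes -> %d unique", len(genomes), len(representatives))

    # -- profiles -----------------------------------------------------------
    profile_dir = outdir / "02_profiles"
    profile_dir.mkdir(exist_ok=True)
    if cfg.profiles_dir:
        profiles = [hmm.profile_from_json(p.read_text())
                    for p in sorted(Path(cfg.profiles_dir).glob("*.json"))]
    else:
        if families_dir is None:
            raise ValueError("no families_dir or profiles_dir configured")
        profiles = build_profiles_from_families(
            families_dir, screen_cfg, calibrate=cfg.calibrate,
            decoys=cfg.decoys, seed=cfg.seed)
    for profile in profiles:
        (profile_dir / f"{profile.name}.json").write_text(
            hmm.profile_to_json(profile))

    # -- size filter + marker screen ---------------------------------------
    screen_dir = outdir / "03_screen"
    screen_dir.mkdir(exist_ok=True)
    rep_genomes = [g for g in genomes if g.id in set(representatives)]
    kept = size_filter(rep_genomes, screen_cfg)
    size_filtered = sorted(g.id for g in kept)
    log.info("size filter: %d -> %d genomes", len(rep_genomes), len(kept))

    proteomes = {gid: proteins[gid] for gid in size_filtered}
    screen_result = screen_genomes(proteomes, profiles, screen_cfg)
    selected = sorted(screen_result.selected)
    _write_marker_table(screen_result, profiles, screen_dir / "marker_table.tsv")
    (screen_dir / "selected.txt").write_text(
        "".join(s + "\n" for s in selected))
    log.info("marker screen: %d genomes selected", len(selected))

    # -- orthology ----------------------------------------------------------
    ortho_dir = outdir / "04_orthology"
    ortho_dir.mkdir(exist_ok=True)
    pangenome = None
    ortho_clusters: list = []
    groups: list = []
    if len(selected) >= 2:
        sel_proteomes = {gid: proteomes[gid] for gid in selected}
        hits = orthology.all_vs_all(sel_proteomes, screen_cfg)
        bbhs = orthology.bbh_pairs(hits)
        all_proteins = [(gid, p.id) for gid in selected
                        for p in sel_proteomes[gid]]
        ortho_clusters = orthology.cog_triangles(bbhs, all_proteins)
        pangenome = orthology.build_pangenome(ortho_clusters, selected)
        with open(ortho_dir / "bbh.tsv", "w") as fh:
            fh.write("protein_a\tprotein_b\n")
            for a, b in bbhs:
                fh.write(f"{a}\t{b}\n")
        orthology.write_clusters_tsv(ortho_clusters, ortho_dir / "clusters.tsv")
        orthology.write_pangenome_tsv(pangenome, ortho_dir / "pangenome.tsv")
        log.info("orthology: %d BBH pairs, %d clusters", len(bbhs),
                 len(ortho_clusters))

        # -- network + grouping ---------------------------------------------
        net_dir = outdir / "05_network"
        net_dir.mkdir(exist_ok=True)
        grouping.export_bipartite_network(pangenome, net_dir / "network.graphml",
                                          net_dir / "edges.tsv")
        groups = grouping.make_groups(pangenome,
                                      screen_cfg.group_similarity_threshold)
        grouping.write_groups_tsv(groups, net_dir / "groups.tsv")
        n_single = sum(1 for g in groups if g.is_singleton)
        log.info("grouping: %d groups, %d singletons",
                 len(groups) - n_single, n_single)

    # -- classification -----------------------------------------------------
    call_dir = outdir / "06_calls"
    call_dir.mkdir(exist_ok=True)
    genome_by_id = {g.id: g for g in genomes}
    calls = []
    for gid in size_filtered:
        features = clf.extract_features(genome_by_id[gid], proteomes[gid],
                                        screen_result.hits_by_protein,
                                        feature_cfg)
        calls.append(clf.classify(gid, features))
    calls_df, counts_df = clf.report_calls(calls, groups,
                                           call_dir / "calls.tsv",
                                           call_dir / "counts.tsv")
    log.info("calls: %s", ", ".join(
        f"{row.state}={row.count}" for row in counts_df.itertuples()))

    return PipelineResult(
        outdir=outdir, config=cfg, dataset=dataset,
        dedup_clusters=dedup_clusters, representatives=representatives,
        size_filtered=size_filtered, profiles=profiles,
        screen_result=screen_result, ortholog_clusters=ortho_clusters,
        pangenome=pangenome, groups=groups, calls=calls,
        calls_table=calls_df, counts_table=counts_df)


def _write_marker_table(result: ScreenResult, profiles, path) -> None:
    names = [p.name for p in profiles]
    with open(path, "w") as fh:
        fh.write("genome_id\t" + "\t".join(names) + "\n")
        for gid in sorted(result.marker_table):
            row = result.marker_table[gid]
            cells = []
            for name in names:
                hit = row.get(name)
                cells.append(f"{hit.bit_score:.1f}" if hit else ".")
            fh.write(gid + "\t" + "\t".join(cells) + "\n")
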