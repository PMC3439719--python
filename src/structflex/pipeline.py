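"""End-to-end orchestration: read/generate -> group -> compare -> report.

Stages mirror the analysis workflow: structures are read (or generated),
clustered into structural groups, filtered by the selection rules, compared
all-against-all within groups (flexibility), assigned secondary structure and
screened for wobble, compared across groups within families (alignment
variation), and audited for evolutionary-distance/gap exceptions.  Every
stage writes a tab-separated table; a manifest records parameters and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from . import alnvar, evodist, grouping, secstruct, superpose, wobble
from .io import ChainStructure, read_dssp_chain, read_pdb_chain
from .synthetic import GeneratorConfig, generate_dataset, write_dataset

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mode: str = "synthetic"              # "synthetic" | "pdb-dir"
    pdb_dir: str | None = None
    metadata: str | None = None
    dssp_dir: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    identity_threshold: float = grouping.DEFAULT_IDENTITY
    resolution_cutoff: float = grouping.DEFAULT_RESOLUTION_CUTOFF
    min_members: int = grouping.DEFAULT_MIN_MEMBERS
    min_family_groups: int = grouping.DEFAULT_MIN_FAMILY_GROUPS
    l_norm_policy: str = "shorter"
    curve_min_states: int = 0
    outdir: str = "structflex_out"
    seed: int = 0
    ligand_filter: str | None = None     # e.g. "free", "complex", "no-ligand"


@dataclass
class RunReport:
    groups: list[grouping.StructuralGroup]
    selection: grouping.SelectionReport
    states3: dict[str, str]                       # structure id -> 3-state string
    within_group: dict[str, list[superpose.SuperpositionResult]]
    wobble_tables: dict[str, wobble.WobbleTable]
    pair_summaries: dict[str, list[wobble.WobblePairSummary]]
    total_vs_single: dict | None
    mutation_chi2: dict | None
    resolution_curve: wobble.ResolutionCoilCurve | None
    group_pairs: list[alnvar.GroupPair]
    site_classes: dict[str, alnvar.SiteClassification]
    state_distribution: dict | None
    exceptions_rmsd: tuple
    exceptions_tm: tuple
    tables: dict[str, str] = field(default_factory=dict)


def load_dataset(pdb_dir, metadata_path) -> dict[str, dict[str, list[ChainStructure]]]:
    """Read every structure listed in the metadata table.

    The table is tab-separated with header
    structure_id, group_id, family_id, chain, file (file relative to the
    metadata's directory).
    """
    root = Path(metadata_path).parent
    families: dict[str, dict[str, list[ChainStructure]]] = {}
    with open(metadata_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(header):
                continue
            sid = parts[idx["structure_id"]]
            gid = parts[idx["group_id"]]
            fid = parts[idx["family_id"]]
            chain = parts[idx["chain"]]
            fpath = root / parts[idx["file"]]
            cs = read_pdb_chain(fpath, chain)
            cs.structure_id = sid
            families.setdefault(fid, {}).setdefault(gid, []).append(cs)
    return families


def _filter_by_ligand(members, ligand_filter):
    if ligand_filter is None:
        return members
    if ligand_filter == "free":
        return [m for m in members if not any(m.ligand_flags.values())]
    if ligand_filter == "complex":
        return [m for m in members if m.ligand_flags.get("in_protein_complex")]
    if ligand_filter == "no-ligand":
        return [m for m in members if not m.ligand_flags.get("has_ligand")]
    raise ValueError(f"unknown ligand filter: {ligand_filter!r}")


def build_groups(families: dict, config: RunConfig) -> list[grouping.StructuralGroup]:
    """Re-cluster all chains of each family at the identity threshold and
    assemble StructuralGroups (MSA + mutation sites)."""
    groups: list[grouping.StructuralGroup] = []
    for fid, by_group in sorted(families.items()):
        chains: list[ChainStructure] = [m for ms in by_group.values()
                                        for m in _filter_by_ligand(ms, config.ligand_filter)]
        by_id = {c.structure_id: c for c in chains}
        clusters = grouping.cluster_identity(
            [(c.structure_id, c.sequence) for c in chains], config.identity_threshold
        )
        for k, ids in enumerate(clusters):
            members = [by_id[i] for i in sorted(ids)]
            gid = f"{fid}-G{k + 1}"
            if len(members) < 2:
                groups.append(grouping.StructuralGroup(gid, members, family_id=fid))
            else:
                g = grouping.make_group(gid, members, fid)
                groups.append(g)
    return groups


def _states_for_group(group, config: RunConfig) -> dict[str, str]:
    states: dict[str, str] = {}
    for m in group.members:
        s3 = None
        if config.dssp_dir:
            entry, chain = m.structure_id.split(":")
            p = Path(config.dssp_dir) / f"{entry}.dssp"
            if p.exists():
                s8 = read_dssp_chain(p, chain, expected_length=len(m))
                s3 = secstruct.reduce_to_three_states(s8)
        if s3 is None:
            s3 = secstruct.assign_secondary_structure(m).states3
        states[m.structure_id] = s3
    return states


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode == "synthetic":
        gen = GeneratorConfig(**{**vars(config.generator), "seed": config.seed})
        families_mem, truths = generate_dataset(gen)
        write_dataset(families_mem, truths, out / "data")
        families = load_dataset(out / "data" / "pdb", out / "data" / "metadata.tsv")
    elif config.mode == "pdb-dir":
        if not config.metadata:
            raise ValueError("pdb-dir mode requires a metadata table")
        families = load_dataset(config.pdb_dir, config.metadata)
    else:
        raise ValueError(f"unknown mode: {config.mode!r}")

    groups = build_groups(families, config)
    kept, selection = grouping.apply_selection_rules(
        groups, config.resolution_cutoff, config.min_members, config.min_family_groups
    )
    # re-assemble MSAs for groups whose membership changed
    kept = [grouping.make_group(g.group_id, g.members, g.family_id) for g in kept]

    states3: dict[str, str] = {}
    within: dict[str, list] = {}
    wobble_tables: dict[str, wobble.WobbleTable] = {}
    pair_summaries: dict[str, list] = {}
    for g in kept:
        states3.update(_states_for_group(g, config))
        comps = []
        for a, b in combinations(g.members, 2):
            comps.append(superpose.structural_align(
                a, b, config.identity_threshold, config.l_norm_policy))
        within[g.group_id] = comps
        gstates = {m.structure_id: states3[m.structure_id] for m in g.members}
        wobble_tables[g.group_id] = wobble.find_wobble_sites(g, gstates)
        pair_summaries[g.group_id] = wobble.group_pair_summaries(g, gstates)

    # wobble total vs max single regression
    tvs = None
    if len(kept) >= 3:
        totals = [wobble_tables[g.group_id].rw for g in kept]
        max_singles = [max((p.wobble_single for p in pair_summaries[g.group_id]), default=0.0)
                       for g in kept]
        if np.ptp(max_singles) > 0:
            tvs = wobble.wobble_total_vs_single(totals, max_singles)

    # mutation-site enrichment, aggregated over groups (Table-1 style 2x2)
    mut_chi2 = None
    agg = {"mut_w": 0, "mut_n": 0, "all_w": 0, "all_n": 0}
    for g in kept:
        t = wobble_tables[g.group_id]
        agg["all_w"] += t.nw
        agg["all_n"] += t.na - t.nw
        for c in g.mutation_sites:
            if 1 <= c <= len(t.wobble_flags):
                agg["mut_w" if t.wobble_flags[c - 1] else "mut_n"] += 1
    if agg["mut_w"] + agg["mut_n"] > 0:
        from . import statkit
        table = [[agg["mut_w"], agg["mut_n"]], [agg["all_w"], agg["all_n"]]]
        try:
            mut_chi2 = {"table": table, "chi2": statkit.chi_square_2x2(table)}
        except ValueError:
            mut_chi2 = {"table": table, "chi2": None}

    # resolution / coil-at-wobble-sites relationship
    pair_states: list[tuple[float, str]] = []
    for g in kept:
        gstates = {m.structure_id: states3[m.structure_id] for m in g.members}
        site_states = wobble_tables[g.group_id].site_states
        res = {m.structure_id: m.resolution for m in g.members}
        ids = g.member_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                if res[a] is None or res[b] is None:
                    continue
                for states in site_states:
                    sa, sb = states.get(a), states.get(b)
                    if sa is not None and sb is not None and sa != sb:
                        pair_states.append((res[a], sa))
                        pair_states.append((res[b], sb))
    curve = None
    if pair_states:
        try:
            curve = wobble.resolution_coil_curve(pair_states, min_states=config.curve_min_states)
        except ValueError:
            curve = None

    # cross-group comparisons within families -> group pairs
    group_pairs: list[alnvar.GroupPair] = []
    by_family: dict[str, list] = {}
    for g in kept:
        by_family.setdefault(g.family_id, []).append(g)
    for fid, fgroups in sorted(by_family.items()):
        for ga, gb in combinations(sorted(fgroups, key=lambda g: g.group_id), 2):
            comps = [superpose.structural_align(a, b, config.identity_threshold,
                                                config.l_norm_policy)
                     for a in ga.members for b in gb.members]
            group_pairs.append(alnvar.GroupPair(ga, gb, comps))

    site_classes: dict[str, alnvar.SiteClassification] = {}
    dists = []
    for gp in group_pairs:
        sc = alnvar.classify_sites(gp)
        site_classes[gp.pair_id] = sc
        dists.append((gp, sc))

    state_distribution = None
    if dists:
        fam_acc: dict[str, list] = {}
        for gp, sc in dists:
            d = alnvar.ss_distribution_by_class(
                gp, sc,
                wobble_tables[gp.group_a.group_id].site_states,
                wobble_tables[gp.group_b.group_id].site_states,
            )
            fam_acc.setdefault(gp.group_a.family_id, []).append(d)
        per_family = {}
        for fid, ds in fam_acc.items():
            per_family[fid] = {
                cls: {s: float(np.mean([d.fractions[cls][s] for d in ds])) for s in "CHE"}
                for cls in alnvar.CLASSES
            }
        state_distribution = {
            "per_family": per_family,
            "average": {
                cls: {s: float(np.mean([pf[cls][s] for pf in per_family.values()]))
                      for s in "CHE"}
                for cls in alnvar.CLASSES
            },
        }

    exc_rmsd = evodist.exception_analysis(group_pairs, "rmsd") if group_pairs else ([], {})
    exc_tm = evodist.exception_analysis(group_pairs, "tm") if group_pairs else ([], {})

    report = RunReport(kept, selection, states3, within, wobble_tables, pair_summaries,
                       tvs, mut_chi2, curve, group_pairs, site_classes,
                       state_distribution, exc_rmsd, exc_tm)
    _write_tables(report, config, out)
    return report


def _write_tables(report: RunReport, config: RunConfig, out: Path) -> None:
    def w(name: str, lines: list[str]):
        p = out / name
        p.write_text("\n".join(lines) + "\n")
        report.tables[name] = str(p)

    w("groups.tsv",
      ["group_id\tfamily_id\tn_members\tmembers\tmutation_sites"] +
      [f"{g.group_id}\t{g.family_id}\t{len(g.members)}\t{','.join(g.member_ids)}\t"
       f"{','.join(map(str, sorted(g.mutation_sites)))}" for g in report.groups])

    w("selection.tsv",
      ["group_id\tstatus\trule"] +
      [f"{gid}\tkept\t-" for gid in report.selection.kept] +
      [f"{gid}\tdropped\t{rule}" for gid, rule in report.selection.dropped])

    rows = ["group_id\tid_a\tid_b\trmsd\ttm_score\tn_aligned"]
    for gid, comps in report.within_group.items():
        for c in comps:
            rows.append(f"{gid}\t{c.id_a}\t{c.id_b}\t{c.rmsd:.4f}\t{c.tm_score:.4f}\t{c.n_aligned}")
    w("within_group_comparisons.tsv", rows)

    rows = ["group_id\tNa\tNw\tRw_percent\tC<=>E\tC<=>H\tH<=>E"]
    for gid, t in report.wobble_tables.items():
        tc = t.type_counts
        rows.append(f"{gid}\t{t.na}\t{t.nw}\t{t.rw:.2f}\t"
                    f"{tc['C<=>E']}\t{tc['C<=>H']}\t{tc['H<=>E']}")
    w("wobble_groups.tsv", rows)

    rows = ["group_id\tid_a\tid_b\twobble_single_percent\tres_a\tres_b"]
    for gid, ps in report.pair_summaries.items():
        for p in ps:
            rows.append(f"{gid}\t{p.id_a}\t{p.id_b}\t{p.wobble_single:.2f}\t"
                        f"{p.resolution_a}\t{p.resolution_b}")
    w("wobble_pairs.tsv", rows)

    if report.resolution_curve is not None:
        c = report.resolution_curve
        rows = ["bin_lower_edge\tcoil_ratio\tn_states"]
        for e, r, n in zip(c.bin_edges, c.coil_ratio, c.counts):
            rows.append(f"{e:.1f}\t{r:.4f}\t{int(n)}")
        rows.append(f"# pcc={c.pcc:.4f} p={c.pcc_p:.3g} slope={c.fit.slope:.4f} "
                    f"intercept={c.fit.intercept:.4f}")
        w("resolution_coil.tsv", rows)

    rows = ["pair_id\trmsd_min\trmsd_max\ttm_min\ttm_max\tRc\tRm\tRg"]
    for gp in report.group_pairs:
        sc = report.site_classes[gp.pair_id]
        rows.append(f"{gp.pair_id}\t{gp.rmsd_min:.4f}\t{gp.rmsd_max:.4f}\t"
                    f"{gp.tm_min:.4f}\t{gp.tm_max:.4f}\t{sc.rc:.2f}\t{sc.rm:.2f}\t{sc.rg:.2f}")
    w("group_pairs.tsv", rows)

    for crit, (records, census) in (("rmsd", report.exceptions_rmsd),
                                    ("tm", report.exceptions_tm)):
        rows = ["pair_id\ted_best\ted_worst\ted_difference\tdelta_openings\t"
                "delta_extensions\tquadrant\texception"]
        for r in records:
            rows.append(f"{r.pair_id}\t{r.ed_best:.2f}\t{r.ed_worst:.2f}\t"
                        f"{r.ed_difference:.2f}\t{r.delta_openings}\t{r.delta_extensions}\t"
                        f"{r.quadrant}\t{int(r.is_exception)}")
        rows.append("# census " + json.dumps(dict(census)))
        w(f"evodist_{crit}.tsv", rows)

    manifest = {
        "mode": config.mode,
        "seed": config.seed,
        "identity_threshold": config.identity_threshold,
        "resolution_cutoff": config.resolution_cutoff,
        "min_members": config.min_members,
        "min_family_groups": config.min_family_groups,
        "l_norm_policy": config.l_norm_policy,
        "n_groups_kept": len(report.groups),
        "n_group_pairs": len(report.group_pairs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    report.tables["manifest.json"] = str(out / "manifest.json")
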