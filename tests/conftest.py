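"""Shared fixtures: generated datasets and analyzed pipeline runs.

Everything is generated at test time from seeded configurations; no data
files ship with the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from structflex import grouping, secstruct, wobble
from structflex.pipeline import RunConfig, run_pipeline
from structflex.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic dataset: 3 families x 3 groups x 6 structures."""
    return generate_dataset(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def analyzed_groups(default_dataset):
    """Per-group wobble analysis of the default dataset."""
    families, truths = default_dataset
    out = []
    for truth in truths:
        for gid in truth.group_ids:
            members = families[truth.family_id][gid]
            group = grouping.make_group(gid, members, truth.family_id)
            states = {
                m.structure_id: secstruct.assign_secondary_structure(m).states3
                for m in members
            }
            table = wobble.find_wobble_sites(group, states)
            pairs = wobble.group_pair_summaries(group, states)
            out.append({"truth": truth, "group": group, "states": states,
                        "table": table, "pairs": pairs})
    return out


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory):
    """One end-to-end pipeline run on a compact synthetic dataset."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    cfg = RunConfig(outdir=str(outdir), seed=5,
                    generator=GeneratorConfig(n_families=2, groups_per_family=3,
                                              structures_per_group=5))
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
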