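"""Shared fixtures: a hand-built Crown-like toy backbone and synthetic cohorts."""

from __future__ import annotations

import pytest

from msylineage import backbone as bb
from msylineage import synthdata as sd

TOY_NEWICK = "((('daC_Ao-aA1a')daC_A,(daC_T1a)daC_T1x)daC,(nc1)NC)root;"
TOY_PANEL = """id,marker_class,ancestral,derived,edge
rAX,SNP,T,C,daC
rW,SNP,A,G,daC_A
rY,SNP,C,T,daC_Ao-aA1a
tv,SNP,G,A,daC_T1x
t1,SNP,C,G,daC_T1a
nv,SNP,A,T,NC
n1,SNP,A,C,nc1
"""


@pytest.fixture(scope="session")
def toy_tree() -> bb.BackboneTree:
    """Six-haplotype backbone: a Crown clade (daC) with an Arabian-like
    terminal and an internal branching point, plus one non-Crown lineage."""
    panel = bb.parse_variant_panel(TOY_PANEL)
    return bb.parse_backbone(TOY_NEWICK, panel, crown_root="daC")


@pytest.fixture(scope="session")
def bundle_small() -> sd.TruthBundle:
    """30-tip clean-genotyping cohort (no masking, no error)."""
    return sd.simulate_bundle(
        sd.SimParams(n_tips=30, seed=11, missing_rate=0.0)
    )


@pytest.fixture(scope="session")
def bundle_masked() -> sd.TruthBundle:
    """60-tip cohort with 30% missingness and zero genotyping error."""
    return sd.simulate_bundle(sd.SimParams(n_tips=60, seed=23))


@pytest.fixture(scope="session")
def bundle_default() -> sd.TruthBundle:
    """Cohort at the generator's default study conditions."""
    return sd.simulate_bundle(sd.SimParams(seed=7))


@pytest.fixture(scope="session")
def bundle_kingman() -> sd.TruthBundle:
    """Population-sample cohort (coalescent genealogy, short terminal
    branches) in which tips share haplotypes, as breed cohorts do."""
    return sd.simulate_bundle(
        sd.SimParams(n_tips=120, tree_model="kingman", seed=13)
    )
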