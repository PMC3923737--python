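import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from types import SimpleNamespace

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: fixtures generated, cleaned, filtered and run
    through precursor discovery once per session."""
    from seedmir.synthetic import SynthConfig, build_world, generate_srna_library
    from seedmir.preprocess import (quality_filter, trim_adapters,
                                    length_filter, collapse_tags)
    from seedmir.ncrna import classify_tags, remove_classified
    from seedmir.discovery import (DiscoveryConfig, anchor_tags,
                                   discover_precursors)
    from seedmir.folding import default_engine

    cfg = SynthConfig(seed=FIXTURE_SEED)
    world = build_world(cfg)
    reads, truth = generate_srna_library(world)
    cleaned = quality_filter(reads)
    trimmed = trim_adapters(cleaned, cfg.adapter_3p)
    sized = length_filter(trimmed)
    tags = collapse_tags(sized)
    refs = {c: [s for (_, s) in world.ncrna_refs[c]] for c in world.ncrna_refs}
    classified = classify_tags(tags, refs)
    retained = remove_classified(classified)
    mature_seqs = {s for _, s in world.mature_reference}
    accepted, rejected = discover_precursors(
        retained, world.contigs, default_engine(),
        DiscoveryConfig.preset("strict"), mature_seqs)
    anchors = anchor_tags(retained, world.contigs)
    return SimpleNamespace(
        cfg=cfg, world=world, reads=reads, truth=truth, cleaned=cleaned,
        sized=sized, tags=tags, classified=classified, retained=retained,
        mature_seqs=mature_seqs, accepted=accepted, rejected=rejected,
        anchors=anchors)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
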