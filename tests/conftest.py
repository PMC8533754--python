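import numpy as np
import pandas as pd
import pytest

import circprio as cp
from circprio import junction_detection as jd
from circprio import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_annotation():
    return sd.generate_annotation(20, seed=7)


@pytest.fixture(scope="session")
def two_group_design():
    return sd.make_design(
        contexts=("ctx",), groups=("control", "treatment"), n_replicates=4
    )


@pytest.fixture(scope="session")
def experiment(toy_annotation, two_group_design):
    """A small two-fraction experiment with error-free reads and detections.

    One exon-repetition transcript and one circle are pinned to high
    abundance so both back-splice species are well supported.
    """
    ann = toy_annotation
    # the zero-effect entry pins an exon-repetition transcript onto G0005
    effects = [
        sd.Effect("G0003", sd.CIRCLE, -1.0),
        sd.Effect("G0005", sd.LINEAR_BACKSPLICED, 0.0),
    ]
    pool, truth = sd.simulate_transcriptome(
        ann,
        two_group_design,
        circ_rate=0.4,
        exonrep_rate=0.1,
        effect_model=effects,
        abundance_override={
            ("G0003", sd.CIRCLE): 50.0,
            ("G0005", sd.LINEAR_BACKSPLICED): 40.0,
        },
        seed=11,
    )
    polya, rnaser = sd.prepare_fractions(pool, seed=12)
    reads_p = sd.sample_reads(polya, ann, 1500, seed=13)
    reads_r = sd.sample_reads(rnaser, ann, 1500, seed=14)
    lib = jd.build_junction_library(ann)
    counts_p = jd.detect_junction_reads(reads_p, lib)
    counts_r = jd.detect_junction_reads(reads_r, lib)
    return {
        "annotation": ann,
        "design": two_group_design,
        "pool": pool,
        "truth": truth,
        "polya_pool": polya,
        "rnaser_pool": rnaser,
        "reads_polya": reads_p,
        "reads_rnaser": reads_r,
        "library": lib,
        "counts_polya": counts_p,
        "counts_rnaser": counts_r,
    }
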