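import numpy as np
import pandas as pd
import pytest

from mrcausal.datatypes import (
    INSTRUMENT_COLUMNS,
    CohortConfig,
    GenotypeMatrix,
    InstrumentSet,
    SnpSpec,
)
from mrcausal.instruments import harmonize_instruments
from mrcausal.synthetic import study_like_panel, simulate_two_sample_study


def make_snp(snp_id="rs1", chrom="1", pos=1_000_000, ea="A", oa="G", maf=0.3,
             block=0, gamma=0.0, alpha=0.0):
    return SnpSpec(snp_id=snp_id, chrom=chrom, pos_bp=pos, effect_allele=ea,
                   other_allele=oa, maf=maf, ld_block=block, gamma_true=gamma,
                   alpha_true=alpha)


def geno_from_columns(columns: dict[str, list], positions=None, chroms=None):
    """GenotypeMatrix from explicit dosage columns keyed by snp_id."""
    ids = list(columns)
    n = len(next(iter(columns.values())))
    panel = []
    for j, sid in enumerate(ids):
        panel.append(
            make_snp(sid, chrom=(chroms or {}).get(sid, "1"),
                     pos=(positions or {}).get(sid, 1_000_000 + j * 1000))
        )
    dos = np.column_stack([np.asarray(columns[sid], dtype=float) for sid in ids])
    return GenotypeMatrix(sample_ids=[f"I{i}" for i in range(n)], panel=panel,
                         dosages=dos)


def iset_from_arrays(gamma, se_gamma, big_gamma, se_big_gamma) -> InstrumentSet:
    k = len(gamma)
    table = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(k)],
            "effect_allele": ["A"] * k,
            "other_allele": ["G"] * k,
            "gamma": np.asarray(gamma, float),
            "se_gamma": np.asarray(se_gamma, float),
            "big_gamma": np.asarray(big_gamma, float),
            "se_big_gamma": np.asarray(se_big_gamma, float),
            "eaf_exposure": [0.3] * k,
            "eaf_outcome": [0.3] * k,
            "flipped": [False] * k,
            "strand_swapped": [False] * k,
        },
        columns=INSTRUMENT_COLUMNS,
    )
    return InstrumentSet(table=table)


@pytest.fixture(scope="session")
def study_panel():
    """18 independent small-effect instruments, the study-like preset."""
    return study_like_panel(k=18, seed=11)


@pytest.fixture(scope="session")
def study_iset(study_panel):
    """Harmonized instrument set from one no-pleiotropy two-sample study."""
    cfg_a = CohortConfig(n_individuals=20_000, causal_beta=2.4, seed=101)
    cfg_b = CohortConfig(n_individuals=20_000, causal_beta=2.4, seed=202)
    exp, out, truth = simulate_two_sample_study(study_panel, cfg_a, cfg_b)
    return harmonize_instruments(exp, out), truth
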