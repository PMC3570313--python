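import numpy as np
import pytest

import ogttfda as og
from ogttfda import fpca as fpca_mod
from ogttfda import simulate as sim_mod
from ogttfda import smoothing as smooth_mod
from ogttfda import summaries as sum_mod


@pytest.fixture(scope="session")
def basis():
    return og.build_basis()


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort used throughout: n=1000, fixed seed."""
    cfg = og.GeneratorConfig(n_subjects=1000, seed=20240117)
    cohort = sim_mod.simulate_cohort(cfg)
    return cfg, cohort


@pytest.fixture(scope="session")
def default_pipeline(default_cohort, basis):
    """Filtered cohort, GCV fit, FPCA and summaries on the default cohort."""
    cfg, cohort = default_cohort
    retained, report = og.filter_complete(cohort)
    Y = retained.glucose_matrix()
    fit = smooth_mod.fit_with_gcv(Y, basis, subject_ids=retained.subject_ids)
    fp = fpca_mod.run_fpca(fit)
    summaries = sum_mod.summarize_cohort(retained)
    return {
        "config": cfg,
        "cohort": cohort,
        "retained": retained,
        "report": report,
        "Y": Y,
        "fit": fit,
        "fpca": fp,
        "summaries": summaries,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_record(values, subject_id="s", **kw):
    return og.GlucoseRecord(
        subject_id=subject_id,
        times=og.CANONICAL_TIMES,
        values=tuple(float(v) for v in values),
        **kw,
    )


@pytest.fixture()
def record_factory():
    return make_record
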