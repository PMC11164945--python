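import numpy as np
import pytest

from fedliver.synthdata import (
    S0,
    S1PLUS,
    CohortConfig,
    PatientRecord,
    generate_cohort,
    make_test_split,
)


def make_patient(
    i: int, binary_class: str = S0, site: str = "private_like", grade: int | None = None
) -> PatientRecord:
    """Lightweight patient factory for partition/split tests (no images)."""
    if grade is None:
        grade = 0 if binary_class == S0 else 2
    return PatientRecord(
        patient_id=f"p{i:05d}",
        site_of_origin=site,
        grade=grade,
        binary_class=binary_class,
        sex="F",
        age=50.0,
        bmi=30.0,
    )


def make_pool(n_s0: int, n_s1: int, site: str = "private_like") -> list[PatientRecord]:
    return [make_patient(i, S0, site) for i in range(n_s0)] + [
        make_patient(n_s0 + i, S1PLUS, site) for i in range(n_s1)
    ]


@pytest.fixture(scope="session")
def default_cohort():
    """The full two-site cohort at default patient counts (no images)."""
    return generate_cohort(CohortConfig.default(seed=0))


@pytest.fixture(scope="session")
def default_split(default_cohort):
    return make_test_split(default_cohort, n_test_per_site=10, seed=0)


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """Small-image profile used wherever pixels are actually rendered."""
    return CohortConfig.tiny(seed=0, size=64, images_per_patient=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def paired_bootstrap_p(scores_a, scores_b, labels, n_boot=100_000, seed=0):
    """Two-sided bootstrap p-value for a paired AUC difference.

    Independent oracle for the DeLong test: resamples cases with replacement
    (keeping the pairing), computes both AUCs per resample, and returns twice
    the smaller tail of the bootstrap difference distribution around zero.
    """
    from scipy.stats import rankdata

    rng_ = np.random.default_rng(seed)
    labels = np.asarray(labels)
    n = len(labels)
    diffs: list[np.ndarray] = []
    kept = 0
    while kept < n_boot:
        idx = rng_.integers(0, n, size=(n_boot, n))
        lab = labels[idx]
        npos = lab.sum(axis=1)
        valid = (npos > 0) & (npos < n)
        idx, lab, npos = idx[valid], lab[valid], npos[valid]

        def auc(mat):
            r = rankdata(mat, axis=1)
            u = (r * lab).sum(axis=1) - npos * (npos + 1) / 2
            return u / (npos * (n - npos))

        d = auc(np.asarray(scores_a)[idx]) - auc(np.asarray(scores_b)[idx])
        take = min(len(d), n_boot - kept)
        diffs.append(d[:take])
        kept += take
    all_d = np.concatenate(diffs)
    frac = np.mean(all_d < 0) + 0.5 * np.mean(all_d == 0)
    return 2 * min(frac, 1 - frac)
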