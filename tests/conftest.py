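"""Shared fixtures: small hand-built cohorts and one session-scoped
fitted model on the default three-class synthetic cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import graftrisk as gr
from graftrisk.data import Cohort, FitResult, JointModelParams, SubjectProfile
from graftrisk.estimation import FitConfig
from graftrisk.links import LinkSpec


def make_profile(sid="S1", **kw) -> SubjectProfile:
    base = dict(
        subject_id=sid,
        donor_age_ge60=0,
        ndsa_pre=0,
        proteinuria_m12=0.1,
        prot_gt_0275=0,
        acute_rejection=0,
        ar_time=None,
        dndsa=0,
        dndsa_time=None,
        entry_time=0.0,
        event_time=8.0,
        event=0,
    )
    base.update(kw)
    return SubjectProfile(**base)


def make_cohort(n=5, seed=0, **profile_kw) -> Cohort:
    """Small deterministic cohort with 4 visits per subject."""
    rng = np.random.default_rng(seed)
    subjects, rows = [], []
    for i in range(n):
        sid = f"S{i + 1}"
        subjects.append(
            make_profile(
                sid,
                event_time=float(2.0 + 6.0 * rng.random()),
                event=int(rng.random() < 0.4),
                ndsa_pre=int(rng.random() < 0.3),
                **profile_kw,
            )
        )
        for t in (0.1, 0.5, 1.0, 1.5):
            rows.append(
                {
                    "subject_id": sid,
                    "t": t + 0.01 * rng.random(),
                    "y": float(120 + 30 * rng.standard_normal()),
                }
            )
    return Cohort(subjects, pd.DataFrame(rows))


def true_params_fitted_convention(cfg: gr.GeneratorConfig) -> JointModelParams:
    """Generator truth re-expressed in the estimation convention.

    The generator draws noise with SD ``cfg.sigma`` on its (identity)
    latent scale; at fit time the residual SD is fixed to 1 and the link
    slope carries the scale, so truth maps to link slope b = sigma,
    beta -> beta/sigma, B -> B/sigma^2.
    """
    b = cfg.sigma
    link = LinkSpec("linear", None, np.array([0.0, b]), cfg.link.y_range)
    return JointModelParams(
        n_classes=cfg.n_classes,
        xi=np.asarray(cfg.xi, float),
        beta=np.asarray(cfg.beta, float) / b,
        B=np.asarray(cfg.B, float) / b**2,
        sigma=1.0,
        link=link,
        zeta=np.asarray(cfg.zeta, float),
        delta=np.asarray(cfg.delta, float),
    )


def fit_result_at(params: JointModelParams, n_subjects: int = 1) -> FitResult:
    """Wrap fixed parameters as a FitResult (zero parameter uncertainty)."""
    from graftrisk.estimation import ParamPacker

    packer = ParamPacker.for_params(params)
    p = packer.n_params
    return FitResult(
        params=params,
        loglik=np.nan,
        vcov=np.zeros((p, p)),
        n_params=p,
        criteria={},
        posterior=np.full((n_subjects, params.n_classes), 1.0 / params.n_classes),
        modal_class=np.zeros(n_subjects, int),
        convergence={"status": "fixed"},
        meta={},
    )


@pytest.fixture(scope="session")
def paper_cohort():
    """Default three-class cohort in delayed-entry mode: the >=1-year
    inclusion rule enters the likelihood as left truncation, so the
    fitted model is correctly specified for the sampled law."""
    cfg = gr.paper_like_preset()
    cfg.n_subjects = 600
    cfg.delayed_entry = True
    cohort, truth = gr.generate_cohort(cfg, seed=42)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def paper_fit(paper_cohort):
    _, cohort, _ = paper_cohort
    return gr.fit(
        cohort,
        3,
        link_family="linear",
        config=FitConfig(n_starts=2, seed=0, compute_vcov=True),
    )


@pytest.fixture(scope="session")
def truth_fit(paper_cohort):
    cfg, cohort, _ = paper_cohort
    return fit_result_at(true_params_fitted_convention(cfg), cohort.n_subjects)
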