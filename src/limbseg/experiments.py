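"""Desk-scale end-to-end segmentation experiments on phantom cohorts.

This module wires the full pipeline together at a problem size a single
CPU handles in minutes: an 11-subject phantom cohort (48x48 in-plane, 96
axial slices, 6 muscle classes), a leave-one-out subject split (8 train /
2 validation / 1 test), optional deformation-augmented copies of the
originals, slice-wise training of a chosen architecture, and per-muscle
evaluation of the held-out subject.  It is the programmatic counterpart of
the ``limbseg`` command-line pipeline and the basis of the worked example
in the README.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluation import EvaluationReport, evaluate_subject
from .nn import NetworkConfig, build_network, predict_labelmap
from .phantom import PhantomSpec, PhantomSubject, deform_subject, generate_phantom
from .schema import synthetic_schema
from .training import LossCurve, SplitPlan, TrainConfig, make_split, slice_stream, train_model

DESK_SPEC = dict(n_classes=6, grid_shape=(96, 48, 48))
AUG_AMPLITUDE_MM = 3.0
AUG_SMOOTHNESS_MM = 8.0


@dataclass
class ExperimentResult:
    variant: str
    plan: SplitPlan
    curve: LossCurve
    report: EvaluationReport
    network: object

    @property
    def mean_dsc(self) -> float:
        return self.report.summary["dsc_mean"]


def build_desk_cohort(seed: int, n_subjects: int = 11, augmented: bool = False):
    """Originals plus (optionally) one deformed copy of each original.

    The deformed copy of subject i carries provenance (fixed = subject
    i+1, moving = subject i), so the split logic later excludes the copies
    that involve the held-out test subject.
    """
    spec = PhantomSpec(seed=seed, **DESK_SPEC)
    originals = [
        generate_phantom(spec, i, subject_id=f"S{i:02d}") for i in range(1, n_subjects + 1)
    ]
    augmented_subjects: list[PhantomSubject] = []
    if augmented:
        for idx, moving in enumerate(originals):
            fixed = originals[(idx + 1) % len(originals)]
            augmented_subjects.append(
                deform_subject(
                    moving,
                    amplitude=AUG_AMPLITUDE_MM,
                    smoothness=AUG_SMOOTHNESS_MM,
                    field_seed=(seed * 131 + idx + 1) % (2**31 - 1),
                    fixed_id=fixed.subject_id,
                )
            )
    return spec, originals, augmented_subjects


def run_desk_experiment(
    variant: str = "unet",
    seed: int = 0,
    augmented: bool = False,
    epochs: int = 20,
    slice_step: int = 2,
    n_subjects: int = 11,
    verbose: bool = False,
) -> ExperimentResult:
    """Train one architecture on a phantom cohort and evaluate the held-out subject."""
    spec, originals, augmented_subjects = build_desk_cohort(seed, n_subjects, augmented)
    test_id = originals[-1].subject_id
    plan = make_split(
        [o.subject_id for o in originals], augmented_subjects, test_id, seed=seed
    )
    by_id = {s.subject_id: s for s in originals + augmented_subjects}
    config = NetworkConfig(variant=variant, n_muscle_classes=spec.n_classes)
    train_stream = slice_stream(
        [by_id[s] for s in plan.train_subjects], nodes=config.spatial_nodes, slice_step=slice_step
    )
    val_stream = slice_stream(
        [by_id[s] for s in plan.val_subjects], nodes=config.spatial_nodes, slice_step=slice_step
    )
    network = build_network(config, seed=seed)
    network, curve = train_model(
        network, train_stream, val_stream, TrainConfig(epochs=epochs, seed=seed), verbose=verbose
    )
    test_subject = by_id[test_id]
    pred = predict_labelmap(network, test_subject.image)
    report = evaluate_subject(
        pred, test_subject.labels, synthetic_schema(spec.n_classes), subject_id=test_id
    )
    return ExperimentResult(
        variant=variant, plan=plan, curve=curve, report=report, network=network
    )
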