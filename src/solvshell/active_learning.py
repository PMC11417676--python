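"""The active-learning driver.

One AL cycle: run several independent MD trajectories with the current
potential for n^3 + 2 fs (n is the MD-run index, starting at 0), screen every
sampled frame with the SOAP similarity selector against the current training
set, label accepted frames with the reference calculator, append them, and
retrain.  If a cycle selects nothing, n increases and a longer MD run is
tried; a phase terminates when the cycle cap is reached or a full cycle at
the maximum AL time selects nothing.

Candidates are screened chronologically with trajectories interleaved
round-robin, and the training set is updated between screenings, so
near-duplicate frames from parallel trajectories are not all accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .md import ThermostatSpec, initialize_state, run_md
from .model import FeatureSpec, LinearMLP, NormalEquations, fit
from .reference import label_dataset
from .soap import SoapSpec, global_descriptor, similarity_select
from .structures import Configuration, LabeledDataset

logger = logging.getLogger(__name__)


def al_md_time(n: int) -> float:
    """MD duration (fs) of AL run index n: n^3 + 2, n starting at 0."""
    if n < 0 or int(n) != n:
        raise ValueError("run index must be a non-negative integer")
    return float(n**3 + 2)


@dataclass
class ALConfig:
    """Settings of one active-learning phase."""

    k_T: float = 0.999
    soap: SoapSpec = field(default_factory=SoapSpec)
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    n_parallel: int = 10
    max_al_time: float = 3000.0       # fs
    max_cycles: int = 30
    temperature: float = 400.0
    dt: float = 0.5
    sample_every: int = 10
    restraints: tuple = ()
    seed: int = 0
    ridge: float = 1e-4
    ridge_3body: float = 0.1
    force_weight: float = 0.1
    max_label_force: float = 150.0   # kcal/mol/Å; reject harder-distorted candidates
    phase: str = "phase-0"

    def __post_init__(self):
        if not (0.0 < self.k_T <= 1.0):
            raise ValueError("k_T must be in (0, 1]")
        if self.max_al_time <= 0:
            raise ValueError("max_al_time must be positive")
        if self.n_parallel < 1:
            raise ValueError("need at least one MD run per cycle")


@dataclass
class ALState:
    """Mutable state of the AL loop."""

    n: int = 0
    cycle: int = 0
    dataset: LabeledDataset = field(default_factory=lambda: LabeledDataset([]))
    model: LinearMLP | None = None
    descriptors: list = field(default_factory=list)   # cached global SOAP descriptors
    normal_eq: NormalEquations | None = None          # incremental fit accumulator
    history: list = field(default_factory=list)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


def _ensure_descriptors(state: ALState, soap: SoapSpec) -> None:
    while len(state.descriptors) < len(state.dataset):
        cfg = state.dataset[len(state.descriptors)]
        state.descriptors.append(global_descriptor(cfg, soap))


def _retrain(state: ALState, al: ALConfig) -> None:
    if state.normal_eq is None:
        state.normal_eq = NormalEquations(al.feature_spec, force_weight=al.force_weight)
    # accumulate only configs not yet folded into the normal equations
    while state.normal_eq.n_configs < len(state.dataset):
        state.normal_eq.add(state.dataset[state.normal_eq.n_configs])
    state.model = state.normal_eq.solve(al.ridge, al.ridge_3body)


def inject_structures(state: ALState, configs, al: ALConfig, reference) -> int:
    """Manually add externally chosen structures (labelled, logged, retrained).

    Mirrors hand-curated additions a practitioner makes when the AL loop
    misses a region (e.g. dissociated-ligand structures); returns the number
    actually added.
    """
    labelled = label_dataset(configs, reference)
    for cfg in labelled:
        cfg.tags["provenance"] = f"{al.phase}:manual"
        state.dataset.append(cfg)
    if len(labelled):
        _ensure_descriptors(state, al.soap)
        _retrain(state, al)
    state.history.append(
        {"phase": al.phase, "event": "manual-injection", "n": state.n,
         "added": len(labelled), "dataset_size": len(state.dataset)}
    )
    return len(labelled)


def al_cycle(state: ALState, start: Configuration, al: ALConfig, reference) -> ALState:
    """One AL cycle: parallel MD, similarity screening, labelling, retraining."""
    if state.model is None:
        raise ValueError("al_cycle requires a model trained on the current dataset")
    md_time = min(al_md_time(state.n), al.max_al_time)
    n_steps = max(int(round(md_time / al.dt)), 1)
    sample_every = min(al.sample_every, n_steps)

    # n_parallel trajectories from the same start, seed-varied velocities
    trajectories = []
    for j in range(al.n_parallel):
        seed = (al.seed * 100_003 + state.cycle * 1009 + state.n * 101 + j) % (2**31)
        st = initialize_state(start, al.temperature, seed=seed)
        res = run_md(
            st, state.model,
            thermostat=ThermostatSpec("csvr", al.temperature, 100.0),
            restraints=list(al.restraints),
            n_steps=n_steps, dt=al.dt, sample_every=sample_every,
        )
        if not res.stable:
            logger.warning("AL MD run %d at n=%d went unstable after %d frames",
                           j, state.n, len(res.trajectory))
        trajectories.append(res.trajectory)

    _ensure_descriptors(state, al.soap)
    selected = 0
    screened = 0
    rejected_distorted = 0
    max_k_seen = 0.0
    # round-robin over trajectories, chronological within each
    depth = max((len(t) for t in trajectories), default=0)
    for frame_i in range(depth):
        for traj in trajectories:
            if frame_i >= len(traj):
                continue
            cand = traj[frame_i]
            desc = np.array(state.descriptors) if state.descriptors else None
            rec = similarity_select(cand, state.dataset, al.soap, al.k_T,
                                    training_descriptors=desc)
            screened += 1
            max_k_seen = max(max_k_seen, rec.max_similarity)
            if rec.selected:
                labelled = label_dataset([cand], reference)
                if len(labelled):
                    cfg = labelled[0]
                    if float(np.abs(cfg.forces).max()) > al.max_label_force:
                        # overly distorted structure: labelling it would let a
                        # huge-residual outlier dominate the squared loss
                        rejected_distorted += 1
                        continue
                    cfg.tags["provenance"] = f"{al.phase}:al"
                    state.dataset.append(cfg)
                    state.descriptors.append(rec.descriptor)
                    selected += 1

    state.history.append(
        {"phase": al.phase, "event": "cycle", "n": state.n, "md_time_fs": md_time,
         "candidates": screened, "selected": selected,
         "rejected_distorted": rejected_distorted, "max_K": max_k_seen,
         "dataset_size": len(state.dataset)}
    )
    state.cycle += 1
    if selected == 0:
        state.n += 1
    else:
        _retrain(state, al)
    return state


def run_al_phase(
    init: LabeledDataset,
    start: Configuration,
    al: ALConfig,
    reference,
) -> tuple[LabeledDataset, LinearMLP, pd.DataFrame]:
    """Run AL cycles until the cycle cap, or until a full cycle at the
    maximum AL time selects nothing.  Deterministic per al.seed."""
    state = ALState(dataset=LabeledDataset(list(init.configs)))
    if len(state.dataset) == 0:
        raise ValueError("phase needs a non-empty initial dataset (bootstrap first)")
    _retrain(state, al)
    _ensure_descriptors(state, al.soap)
    for _cycle in range(al.max_cycles):
        md_time = min(al_md_time(state.n), al.max_al_time)
        at_cap = md_time >= al.max_al_time
        before = len(state.dataset)
        state = al_cycle(state, start, al, reference)
        if at_cap and len(state.dataset) == before:
            break
    return state.dataset, state.model, state.history_frame()


def bootstrap_dataset(configs, reference, soap: SoapSpec | None = None) -> LabeledDataset:
    """Label an initial pool of structures to seed the first AL phase."""
    ds = label_dataset(configs, reference)
    for cfg in ds:
        cfg.tags.setdefault("provenance", "bootstrap")
    return ds
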