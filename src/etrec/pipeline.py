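"""End-to-end simulation pipeline: subject + configuration -> features + PCS.

For one subject-configuration pair the pipeline (i) personalises the
four-layer tissue model, (ii) voxelises it and solves the quasi-static
potential with the configured active electrode(s) driven at the default
amplitude, (iii) extracts the field descriptors Emax / Eavg / Eint over
the innervated region, (iv) maps the potential onto a dermal A-beta
fiber, integrates the passive cable under the biphasic waveform and
extracts Vpeak / Tpeak, and (v) composes the PCS.

The pipeline object is callable with ``(subject, config)`` so it plugs
directly into the recommender, and it memoises per-pair results (the
computation is deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cable import (
    CableParams,
    NeuralFeatures,
    extracellular_drive,
    integrate_cable,
    neural_features,
    node_positions,
)
from .config_space import ElectrodeConfig, electrode_centers, enumerate_configs
from .field import (
    FieldFeatures,
    build_grid,
    electric_field,
    extract_field_features,
    solve_potential,
)
from .runconfig import RunConfig
from .scoring import PCSComponents, compute_pcs
from .tissue import FingertipModel, SubjectDescriptors, personalize_layers

#: Canonical order of the 9-component feature vector
#: x = (Emax, Eint, Eavg, Vpeak, Tpeak, Height, Weight, Age, sex).
FEATURE_NAMES: tuple[str, ...] = (
    "e_max",
    "e_int",
    "e_avg",
    "v_peak_mv",
    "t_peak_s",
    "height_cm",
    "weight_kg",
    "age",
    "sex",
)


@dataclass(frozen=True)
class FeatureRecord:
    """All per-pair pipeline outputs, with the composite score."""

    subject: SubjectDescriptors
    config: ElectrodeConfig
    field: FieldFeatures
    neural: NeuralFeatures
    pcs: PCSComponents

    @property
    def feature_vector(self) -> np.ndarray:
        s = self.subject
        return np.array(
            [
                self.field.e_max,
                self.field.e_int,
                self.field.e_avg,
                self.neural.v_peak_mv,
                self.neural.t_peak_s,
                s.height_cm,
                s.weight_kg,
                s.age,
                float(s.sex),
            ]
        )

    def to_row(self) -> dict:
        row = {"subject_id": self.subject.subject_id, "config": self.config.label}
        row.update(dict(zip(FEATURE_NAMES, self.feature_vector)))
        row.update(
            {
                "e_focus": self.pcs.e_focus,
                "w_neuro": self.pcs.w_neuro,
                "u_pattern": self.pcs.u_pattern,
                "spread_c": self.pcs.spread,
                "pcs": self.pcs.pcs,
            }
        )
        return row


class SimulationPipeline:
    """Deterministic subject x configuration feature generator."""

    def __init__(self, config: RunConfig | None = None):
        self.config = config if config is not None else RunConfig()
        self.cable_params = CableParams.from_geometry(
            self.config.fiber,
            v_th_mv=self.config.v_th_mv,
            k_per_mv=self.config.k_per_mv,
        )
        self._cache: dict[tuple[SubjectDescriptors, ElectrodeConfig], FeatureRecord] = {}

    def __call__(self, subject: SubjectDescriptors, config: ElectrodeConfig) -> FeatureRecord:
        return self.features(subject, config)

    def features(self, subject: SubjectDescriptors, config: ElectrodeConfig) -> FeatureRecord:
        key = (subject, config)
        if key in self._cache:
            return self._cache[key]
        rc = self.config
        model = FingertipModel(
            layers=personalize_layers(subject, rc.layers, rc.personalization),
            subject=subject,
            lateral_extent_mm=rc.lateral_extent_mm,
            effective_frequency_hz=rc.effective_frequency_hz,
        )
        grid = build_grid(model, config, rc.resolution)
        layout = electrode_centers(config)
        try:
            pot = solve_potential(
                grid,
                layout=layout,
                active=rc.active_electrodes,
                current_ma=rc.amplitude_ma,
                tol=rc.solver_tol,
                method=rc.solver_method,
            )
            _, e_mag = electric_field(pot)
            ff = extract_field_features(e_mag, grid, rc.region)
            nodes = node_positions(rc.fiber, layout)
            drive = extracellular_drive(pot, nodes, rc.waveform, rc.dt_s, rc.duration_s)
            traj = integrate_cable(self.cable_params, drive)
            nf = neural_features(traj, self.cable_params)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for subject={subject.subject_id or subject} "
                f"config={config.label}: {exc}"
            ) from exc
        comp = compute_pcs(
            ff, nf, v_th_mv=rc.v_th_mv, k_per_mv=rc.k_per_mv, epsilon=rc.epsilon
        )
        rec = FeatureRecord(subject=subject, config=config, field=ff, neural=nf, pcs=comp)
        self._cache[key] = rec
        return rec

    def features_table(
        self,
        subjects: list[SubjectDescriptors],
        configs: list[ElectrodeConfig] | None = None,
    ) -> pd.DataFrame:
        """One row per subject-configuration pair, in deterministic order."""
        if configs is None:
            configs = enumerate_configs()
        rows = [self.features(s, c).to_row() for s in subjects for c in configs]
        df = pd.DataFrame(rows)
        df.attrs["config_hash"] = self.config.config_hash()
        return df

    def pcs_values(
        self,
        subject: SubjectDescriptors,
        configs: list[ElectrodeConfig] | None = None,
    ) -> np.ndarray:
        """Computed (not predicted) PCS across configurations for one subject."""
        if configs is None:
            configs = enumerate_configs()
        return np.array([self.features(subject, c).pcs.pcs for c in configs])
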