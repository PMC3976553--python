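"""Run configuration: YAML/JSON schema with human-friendly units.

Files use mm, kPa and kg/m^3; values are converted to SI where the solver
needs them.  Unknown keys are rejected and schema violations report the
offending key and the expected range.  An empty file yields the full default
configuration (friction 0.05, coaptation threshold 50 kPa).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import contact as ct
from . import geometry as geo
from . import materials as mat
from . import solver as sv
from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class AnnulusCfg(_Model):
    ap_diameter: float = Field(30.0, gt=0, description="anteroposterior diameter, mm")
    cc_diameter: float = Field(36.0, gt=0, description="commissural diameter, mm")
    saddle_height: float = Field(4.0, ge=0, description="peak-to-peak saddle height, mm")
    n_samples: int = Field(64, ge=8)


class LeafletCfg(_Model):
    anterior_height: float = Field(23.0, gt=0)
    posterior_height: float = Field(14.0, gt=0)
    commissural_overlap: float = Field(0.08, ge=0)
    billow: float = Field(1.5, ge=0)


class ChordaeCfg(_Model):
    n_marginal_anterior: int = Field(12, ge=0)
    n_marginal_posterior: int = Field(12, ge=0)
    n_strut: int = Field(2, ge=0)
    pm_positions: Optional[list[list[float]]] = None
    branching: bool = False
    segment_length: float = Field(3.0, gt=0, description="chord subdivision target, mm")
    rest_scale: float = Field(1.0, gt=0, description="scale on estimated taut lengths")


class PathologicCfg(_Model):
    annular_dilation: float = Field(1.3, ge=1.0)
    pm_displacement: list[float] = Field(default_factory=lambda: [0.0, 0.0, 0.0])


class ShapeCfg(_Model):
    anterior_half_arc_deg: float = Field(75.0, gt=0, lt=180)
    commissure_gap_deg: float = Field(2.5, ge=0, lt=30)
    funnel_angle_anterior_deg: float = Field(28.0, ge=0, lt=90)
    funnel_angle_posterior_deg: float = Field(42.0, ge=0, lt=90)
    coapt_depth_frac: float = Field(0.45, gt=0, le=1)
    coapt_inplane_frac: float = Field(0.30, ge=0, le=1)


class GeometryCfg(_Model):
    annulus: AnnulusCfg = AnnulusCfg()
    leaflets: LeafletCfg = LeafletCfg()
    chordae: ChordaeCfg = ChordaeCfg()
    shape: ShapeCfg = ShapeCfg()
    target_edge_length: float = Field(2.5, gt=0, description="mm")
    pathologic: Optional[PathologicCfg] = None


class FungCfg(_Model):
    c: float = Field(gt=0, description="kPa")
    a1: float = Field(gt=0)
    a2: float = Field(gt=0)
    a3: float = 0.0
    a4: float = Field(10.0, gt=0)


class OgdenCfg(_Model):
    order: Literal[1, 2] = 1
    mu: list[float] = Field(default_factory=lambda: [1800.0], description="kPa")
    alpha: list[float] = Field(default_factory=lambda: [12.0])


class ChordaeMaterialsCfg(_Model):
    posterior_marginal: OgdenCfg = OgdenCfg()
    anterior_marginal: OgdenCfg = OgdenCfg()
    strut: OgdenCfg = OgdenCfg(mu=[2600.0], alpha=[13.0])


class MaterialsCfg(_Model):
    leaflet_anterior: FungCfg = FungCfg(c=5.0, a1=20.0, a2=14.0, a3=6.0, a4=10.0)
    leaflet_posterior: FungCfg = FungCfg(c=3.0, a1=16.0, a2=12.0, a3=5.0, a4=8.0)
    chordae: ChordaeMaterialsCfg = ChordaeMaterialsCfg()
    thickness_anterior: float = Field(0.69, gt=0, description="mm")
    thickness_posterior: float = Field(0.51, gt=0, description="mm")
    area_posterior_marginal: float = Field(0.27, gt=0, description="mm^2")
    area_anterior_marginal: float = Field(0.29, gt=0, description="mm^2")
    area_strut: float = Field(0.61, gt=0, description="mm^2")
    density: float = Field(1100.0, gt=0, description="kg/m^3")
    poisson: float = Field(0.48, gt=0, lt=0.5)
    tension_only: bool = True


class PressureCfg(_Model):
    peak_kpa: float = Field(13.33, ge=0, description="peak systolic transvalvular pressure")
    interpolation: Literal["linear", "smoothstep"] = "smoothstep"
    knots: Optional[list[list[float]]] = Field(
        None, description="optional [(time s, kPa), ...] overriding the default ramp"
    )


class ClosureCfg(_Model):
    annular_area_contraction: float = Field(0.2, ge=0, lt=1)
    pm_displacement: list[float] = Field(default_factory=lambda: [0.0, 0.0, 0.0])


class SolverCfg(_Model):
    dt: Optional[float] = Field(None, gt=0, description="s; None = auto stable timestep")
    T_end: float = Field(0.25, ge=0, description="s, end diastole to peak systole")
    damping_alpha: float = Field(300.0, ge=0, description="1/s mass-proportional damping")
    mass_scale: float = Field(6.0, ge=1)
    chordae_mass_scale: float = Field(40.0, ge=1)
    output_stride: int = Field(2000, ge=1)
    dt_safety: float = Field(0.5, gt=0, le=1)
    strain_cap: float = Field(0.30, gt=0)
    pressure: PressureCfg = PressureCfg()
    closure: ClosureCfg = ClosureCfg()


class ContactCfg(_Model):
    mode: Literal["full", "leaflets_only"] = "full"
    kn: Optional[float] = Field(None, gt=0, description="N/m; None = auto from timestep")
    kt: Optional[float] = Field(None, ge=0)
    friction: float = Field(0.05, ge=0, lt=1)
    clearance: Optional[float] = Field(None, ge=0, description="mm; None = half thicknesses")
    stiffness_safety: float = Field(1000.0, ge=1)


class ReportCfg(_Model):
    threshold_kpa: float = Field(50.0, ge=0, description="coaptation pressure threshold")


class RunConfig(_Model):
    geometry: GeometryCfg = GeometryCfg()
    materials: MaterialsCfg = MaterialsCfg()
    solver: SolverCfg = SolverCfg()
    contact: ContactCfg = ContactCfg()
    report: ReportCfg = ReportCfg()
    output_dir: str = "out"
    seed: int = 0

    # ---- converters to domain objects -------------------------------------

    def annulus_profile(self) -> geo.AnnulusProfile:
        a = self.geometry.annulus
        return geo.AnnulusProfile(a.ap_diameter, a.cc_diameter, a.saddle_height, a.n_samples)

    def leaflet_spec(self) -> geo.LeafletSpec:
        l = self.geometry.leaflets
        return geo.LeafletSpec(
            l.anterior_height, l.posterior_height, l.commissural_overlap, l.billow
        )

    def chordae_spec(self) -> geo.ChordaeSpec:
        c = self.geometry.chordae
        pm = tuple(tuple(p) for p in c.pm_positions) if c.pm_positions else None
        return geo.ChordaeSpec(
            c.n_marginal_anterior, c.n_marginal_posterior, c.n_strut, pm, c.branching
        )

    def build_geometry(self) -> geo.MVGeometry:
        g = self.geometry
        valve = geo.build_valve(
            self.annulus_profile(),
            self.leaflet_spec(),
            self.chordae_spec(),
            target_edge_length=g.target_edge_length,
            seed=self.seed,
            anterior_half_arc_deg=g.shape.anterior_half_arc_deg,
            commissure_gap_deg=g.shape.commissure_gap_deg,
            funnel_angle_anterior_deg=g.shape.funnel_angle_anterior_deg,
            funnel_angle_posterior_deg=g.shape.funnel_angle_posterior_deg,
            chord_segment_length=g.chordae.segment_length,
            coapt_depth_frac=g.shape.coapt_depth_frac,
            coapt_inplane_frac=g.shape.coapt_inplane_frac,
            rest_scale=g.chordae.rest_scale,
        )
        if g.pathologic is not None:
            valve = geo.make_pathologic_variant(
                valve, g.pathologic.annular_dilation, g.pathologic.pm_displacement
            )
        return valve

    def material_set(self) -> mat.MaterialSet:
        m = self.materials
        return mat.MaterialSet(
            fung_anterior=mat.FungParams(**m.leaflet_anterior.model_dump()),
            fung_posterior=mat.FungParams(**m.leaflet_posterior.model_dump()),
            ogden={
                name: mat.OgdenParams(
                    order=o.order, mu=tuple(o.mu), alpha=tuple(o.alpha)
                )
                for name, o in (
                    ("posterior_marginal", m.chordae.posterior_marginal),
                    ("anterior_marginal", m.chordae.anterior_marginal),
                    ("strut", m.chordae.strut),
                )
            },
            props=mat.TissueProps(
                thickness_anterior=m.thickness_anterior,
                thickness_posterior=m.thickness_posterior,
                area_posterior_marginal=m.area_posterior_marginal,
                area_anterior_marginal=m.area_anterior_marginal,
                area_strut=m.area_strut,
                density=m.density,
                poisson=m.poisson,
            ),
            tension_only=m.tension_only,
        )

    def solver_config(self) -> sv.SolverConfig:
        s = self.solver
        if s.pressure.knots:
            curve = sv.LoadCurve(
                knots=tuple((float(t), float(v) * 1e3) for t, v in s.pressure.knots),
                interpolation=s.pressure.interpolation,
            )
        else:
            curve = sv.LoadCurve.ramp_hold(
                s.T_end, s.pressure.peak_kpa * 1e3, interpolation=s.pressure.interpolation
            )
        return sv.SolverConfig(
            dt=s.dt,
            T_end=s.T_end,
            damping_alpha=s.damping_alpha,
            peak_pressure=s.pressure.peak_kpa * 1e3,
            pressure_curve=curve,
            output_stride=s.output_stride,
            mass_scale=s.mass_scale,
            chordae_mass_scale=s.chordae_mass_scale,
            dt_safety=s.dt_safety,
            strain_cap=s.strain_cap,
            contact_stiffness_safety=self.contact.stiffness_safety,
            seed=self.seed,
        )

    def closure_spec(self) -> geo.ClosureSpec:
        c = self.solver.closure
        return geo.ClosureSpec(c.annular_area_contraction, tuple(c.pm_displacement))

    def contact_domain(self, mode: str | None = None) -> ct.ContactDomain:
        return ct.configure_domain(mode or self.contact.mode)

    def penalty_params(self, kn: float, kt: float | None = None) -> ct.PenaltyParams:
        c = self.contact
        return ct.PenaltyParams(
            kn=c.kn or kn,
            kt=c.kt if c.kt is not None else (c.kn or kt or kn),
            mu_d=c.friction,
            clearance=None if c.clearance is None else c.clearance * 1e-3,
        )


def load_config(path=None, text: str | None = None) -> RunConfig:
    """Load and validate a YAML/JSON configuration; empty input = defaults."""
    if text is None:
        if path is None:
            return RunConfig()
        text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as err:
        msgs = []
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"]) or "<root>"
            msgs.append(f"{loc}: {e['msg']}")
        raise ConfigurationError("invalid configuration: " + "; ".join(msgs)) from None


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 of the fully defaulted configuration."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
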