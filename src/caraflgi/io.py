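"""Configuration files, fixtures, result writers and run manifests."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .bandit import JointState
from .simulate import OperatingCharacteristics, TrialConfig

__all__ = [
    "load_config",
    "dump_config",
    "fixture_worked_example",
    "write_oc_table",
    "RunManifest",
    "write_manifest",
    "load_manifest",
]

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(TrialConfig)}


def load_config(path) -> TrialConfig:
    """Load and validate a trial configuration from YAML or JSON.

    Defaults (Beta(1,1) priors, discount 0.99, 100 Monte-Carlo lookahead
    replications, nominal level 0.05) are filled for missing keys; unknown
    keys are rejected.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return TrialConfig(**raw)


def dump_config(config: TrialConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def fixture_worked_example() -> JointState:
    """Two-arm, binary-covariate state after one success each on arms 00 and 11.

    Starting from Beta(1,1) priors on all four combination arms, a
    covariate-negative patient responded on control and a covariate-positive
    patient responded on the experimental arm, leaving posterior counts
    [(2,1); (1,1); (1,1); (2,1)].  This is the canonical small state used in
    the documentation and tests.
    """
    state = JointState(
        n_levels=2,
        n_treatments=1,
        s=np.array([2.0, 1.0, 1.0, 2.0]),
        f=np.array([1.0, 1.0, 1.0, 1.0]),
        prior_s=np.ones(4),
        prior_f=np.ones(4),
        patients_treated=2,
    )
    return state


def _fmt(x: float) -> str:
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.4f}"


def _fmt_sd(x: float) -> str:
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.2f}"


def write_oc_table(rows, path, metadata: dict | None = None) -> None:
    """Write operating characteristics as a CSV, one row per design.

    ``rows`` is a sequence of ``(label, block_size, oc)`` with every ``oc``
    an :class:`OperatingCharacteristics`.  Two-arm designs report a single
    power column and ENF; multi-arm designs report per-covariate-level
    powers and ENS.  Mixing the two in one table raises.  Means are
    printed at 4 decimals, standard deviations at 2, mirroring the usual
    presentation of trial operating characteristics.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("need at least one design row")
    n_arms = {oc.alloc_prop_mean.size for _, _, oc in rows}
    if len(n_arms) != 1:
        raise ValueError("cannot mix designs with different arm counts in one table")
    two_arm = rows[0][2].alloc_prop_mean.size == 2
    n_levels = rows[0][2].best_prop_mean.size
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        power_cols = (
            ["power"] if two_arm else [f"power_level{z}" for z in range(n_levels)]
        )
        eff_col = "ENF" if two_arm else "ENS"
        header = (
            ["procedure", "b"]
            + power_cols
            + ["N0_prop", "N0_prop_sd"]
            + [f"best_prop_z{z}" for z in range(n_levels)]
            + [f"best_prop_z{z}_sd" for z in range(n_levels)]
            + [eff_col, f"{eff_col}_sd", "p_star", "p_star_sd", "CM_pct", "replications"]
        )
        fh.write(",".join(header) + "\n")
        for label, b, oc in rows:
            power = (
                [_fmt(oc.power)]
                if two_arm
                else [_fmt(v) for v in oc.power_by_level]
            )
            eff = (oc.enf_mean, oc.enf_sd) if two_arm else (oc.ens_mean, oc.ens_sd)
            cells = (
                [label, str(b)]
                + power
                + [_fmt(oc.alloc_prop_mean[0]), _fmt_sd(oc.alloc_prop_sd[0])]
                + [_fmt(v) for v in oc.best_prop_mean]
                + [_fmt_sd(v) for v in oc.best_prop_sd]
                + [_fmt(eff[0]), _fmt_sd(eff[1]), _fmt(oc.pstar_mean), _fmt_sd(oc.pstar_sd)]
                + [f"{oc.cm_pct:.1f}", str(oc.replications)]
            )
            fh.write(",".join(cells) + "\n")


@dataclass
class RunManifest:
    """Traceability record: everything needed to reproduce a run bit-identically."""

    config: dict
    seed: int
    outputs: list
    package_version: str = ""
    gittins_table_hash: str | None = None
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def content_hash(self) -> str:
        payload = json.dumps(
            {"config": self.config, "seed": self.seed, "table": self.gittins_table_hash},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, sort_keys=True)


def load_manifest(path) -> RunManifest:
    with open(path) as fh:
        return RunManifest(**json.load(fh))
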