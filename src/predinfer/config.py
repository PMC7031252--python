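"""Structured (YAML/JSON) configuration for task, cohort and analysis.

A config file holds up to three sections::

    task:      TaskConfig fields (n_trials, hazards, sigma_gen, ...)
    cohort:    n_subjects, dimension correlation matrix, agent-parameter
               defaults and the dimension -> parameter effect map
    analysis:  lr_percentile, moderators, bonferroni m

Missing sections or fields fall back to the package defaults, so an empty
file reproduces the standard study configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .cohort import AgentParams, default_dimension_corr, default_effect_map
from .task import TaskConfig

__all__ = ["load_config", "save_config", "StudyConfig"]


class StudyConfig:
    """Bundle of task config, cohort settings and analysis switches."""

    def __init__(self, task=None, cohort=None, analysis=None):
        cohort = dict(cohort or {})
        self.task = task if isinstance(task, TaskConfig) else TaskConfig.from_dict(task or {})
        self.n_subjects = int(cohort.get("n_subjects", 437))
        corr = cohort.get("dimension_correlation")
        self.dimension_correlation = (
            default_dimension_corr() if corr is None else np.asarray(corr, dtype=float)
        )
        self.agent_defaults = AgentParams(**cohort.get("agent_defaults", {}))
        self.effects = cohort.get("effects", default_effect_map())
        analysis = dict(analysis or {})
        self.lr_percentile = float(analysis.get("lr_percentile", 99.0))
        self.moderators = list(analysis.get("moderators", ["AD", "CIT", "SW"]))
        self.m_bonferroni = int(analysis.get("m_bonferroni", len(self.moderators)))

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "task": self.task.to_dict(),
            "cohort": {
                "n_subjects": self.n_subjects,
                "dimension_correlation": self.dimension_correlation.tolist(),
                "agent_defaults": asdict(self.agent_defaults),
                "effects": self.effects,
            },
            "analysis": {
                "lr_percentile": self.lr_percentile,
                "moderators": self.moderators,
                "m_bonferroni": self.m_bonferroni,
            },
        }


def load_config(path) -> StudyConfig:
    """Read a YAML or JSON study configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = data or {}
    return StudyConfig(task=data.get("task"), cohort=data.get("cohort"),
                       analysis=data.get("analysis"))


def save_config(config: StudyConfig, path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
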