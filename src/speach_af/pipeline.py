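"""Campaign orchestration: scan → mutate → fold → collect.

A *campaign* is one protein: a query sequence, its base a3m alignment, a list
of mutation sets, and a folding plan of ``runs_per_set`` runs ×
``models_per_run`` models per alignment (3 × 5 = 15 by default).  The
unmodified alignment is folded the same number of times, so a campaign of
*k* sets expects ``(k + 1) × 15`` models.  Folding is behind a pluggable
backend contract: the ColabFold adapter shells out to ``colabfold_batch``
(one run per random seed; templates always disabled), while the mock backend
samples the hinge-toy generator with a programmed, deterministic response to
MSA alanization so the whole pipeline is testable without GPU inference.

Runs are materialized under ``out_dir/sets/<set_id>/run<k>/model_<m>.pdb``
with a JSON manifest; completed runs are detected on disk and skipped on
resume, and individual run failures are recorded without aborting the
campaign.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from speach_af.contact_scan import MutationSet, ScanConfig, scan_model
from speach_af.fixtures import HingeToySpec, hinge_model, interface_positions
from speach_af.metrics import ModelEnsemble
from speach_af.msa import emit_campaign, read_a3m
from speach_af.structures import StructureModel, read_model, write_model

__all__ = [
    "Campaign",
    "MockFoldBackend",
    "ColabFoldBackend",
    "run_campaign",
    "top_ranked",
    "measure_hinge_angle",
]


def top_ranked(models: list[StructureModel]) -> StructureModel:
    """Highest mean-pLDDT model — the default model to scan for contacts."""
    if not models:
        raise ValueError("no models to rank")
    return max(models, key=lambda m: float(m.plddt_array().mean()))


@dataclass
class Campaign:
    """A folding campaign plan; JSON round-trippable."""

    query_id: str
    query: str
    base_msa: str
    sets: list[MutationSet]
    runs_per_set: int = 3
    models_per_run: int = 5
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2])
    backend: str = "mock"
    backend_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.seeds) != self.runs_per_set:
            raise ValueError(
                f"need one seed per run: {len(self.seeds)} seeds for "
                f"{self.runs_per_set} runs"
            )

    @property
    def expected_mutant_models(self) -> int:
        return len(self.sets) * self.runs_per_set * self.models_per_run

    @property
    def expected_total_models(self) -> int:
        # +1: the unmodified MSA is also run runs_per_set times
        return (len(self.sets) + 1) * self.runs_per_set * self.models_per_run

    def to_json(self) -> dict:
        return {
            "query_id": self.query_id,
            "query": self.query,
            "base_msa": self.base_msa,
            "sets": [s.to_json() for s in self.sets],
            "runs_per_set": self.runs_per_set,
            "models_per_run": self.models_per_run,
            "seeds": list(self.seeds),
            "backend": self.backend,
            "backend_params": self.backend_params,
        }

    @classmethod
    def from_json(cls, d: dict) -> "Campaign":
        return cls(
            query_id=d["query_id"],
            query=d["query"],
            base_msa=d["base_msa"],
            sets=[MutationSet.from_json(s) for s in d["sets"]],
            runs_per_set=d["runs_per_set"],
            models_per_run=d["models_per_run"],
            seeds=list(d["seeds"]),
            backend=d.get("backend", "mock"),
            backend_params=d.get("backend_params", {}),
        )

    @classmethod
    def from_scan(
        cls,
        model: StructureModel,
        base_msa: str | Path,
        config: ScanConfig | None = None,
        **kwargs,
    ) -> "Campaign":
        """Build a campaign by running the systematic contact scan on a model."""
        aln = read_a3m(base_msa)
        sets, _ = scan_model(model, config)
        return cls(
            query_id=aln.query_id,
            query=aln.query,
            base_msa=str(base_msa),
            sets=sets,
            **kwargs,
        )


class MockFoldBackend:
    """Deterministic test double for the folding backend.

    Samples the hinge-toy conformational generator.  The sampled opening
    angle responds to MSA mutagenesis: the mean hinge angle shifts by
    ``shift_degrees`` times the fraction of toy interface positions whose
    query residue was mutated, so alanizing the inter-domain interface
    measurably opens the toy.  Output is a pure function of the a3m file
    content and the run seed.
    """

    def __init__(
        self,
        spec: HingeToySpec,
        reference_query: str,
        shift_degrees: float = 25.0,
        angle_jitter: float = 2.0,
        models_per_run: int = 5,
    ):
        if len(reference_query) != spec.n_residues:
            raise ValueError(
                f"reference query length {len(reference_query)} != toy length "
                f"{spec.n_residues}"
            )
        self.spec = spec
        self.reference_query = reference_query
        self.shift_degrees = shift_degrees
        self.angle_jitter = angle_jitter
        self.models_per_run = models_per_run
        self.interface = set(interface_positions(spec))

    def programmed_shift(self, msa_query: str) -> float:
        mutated = {
            i
            for i, (a, b) in enumerate(zip(self.reference_query, msa_query), start=1)
            if a != b
        }
        frac = len(mutated & self.interface) / len(self.interface)
        return self.shift_degrees * frac

    def fold(self, msa_path: str | Path, seed: int) -> list[StructureModel]:
        content = Path(msa_path).read_bytes()
        aln = read_a3m(msa_path)
        base_angle = 0.5 * (self.spec.angle_range[0] + self.spec.angle_range[1])
        mean_angle = base_angle + self.programmed_shift(aln.query)
        sub_seed = (int(seed) * 1000003 + zlib.crc32(content)) % (2**31)
        rng = np.random.default_rng(sub_seed)
        models = []
        for m in range(self.models_per_run):
            theta = float(np.clip(rng.normal(mean_angle, self.angle_jitter), 0.5, 179.5))
            phi = (
                float(rng.uniform(*self.spec.angle_range2))
                if self.spec.modes == 2
                else 0.0
            )
            models.append(
                hinge_model(
                    self.spec,
                    theta,
                    phi,
                    noise_rng=rng,
                    model_id=f"seed{seed}_model{m}",
                )
            )
        return models


class ColabFoldBackend:
    """Adapter around the ``colabfold_batch`` executable.

    Each run invokes one batch with ``--random-seed <seed>`` and templates
    disabled; the five ranked PDBs are read back with pLDDT from the B-factor
    column.  Installations whose batch runner ignores ``--random-seed``
    cannot vary models between runs — a documented limitation of the adapter,
    not worked around here.
    """

    def __init__(self, executable: str | None = None, models_per_run: int = 5):
        self.executable = executable or shutil.which("colabfold_batch")
        if self.executable is None:
            raise FileNotFoundError(
                "colabfold_batch not found on PATH; install ColabFold or use "
                "the mock backend"
            )
        self.models_per_run = models_per_run

    def fold(self, msa_path: str | Path, seed: int) -> list[StructureModel]:
        msa_path = Path(msa_path)
        work = msa_path.parent / f"cf_seed{seed}_{msa_path.stem}"
        work.mkdir(exist_ok=True)
        cmd = [
            self.executable,
            str(msa_path),
            str(work),
            "--num-models",
            str(self.models_per_run),
            "--random-seed",
            str(seed),
        ]
        subprocess.run(cmd, check=True, capture_output=True)
        pdbs = sorted(work.glob("*_unrelaxed_rank_*.pdb")) or sorted(work.glob("*.pdb"))
        if len(pdbs) < self.models_per_run:
            raise RuntimeError(
                f"colabfold_batch produced {len(pdbs)} models, expected "
                f"{self.models_per_run}"
            )
        return [
            read_model(p, plddt_from_bfactor=True, model_id=f"seed{seed}_model{m}")
            for m, p in enumerate(pdbs[: self.models_per_run])
        ]


def _log(log_path: Path, event: str, **fields) -> None:
    with log_path.open("a") as fh:
        fh.write(json.dumps({"event": event, **fields}) + "\n")


def run_campaign(
    campaign: Campaign,
    out_dir: str | Path,
    backend=None,
) -> tuple[ModelEnsemble, dict]:
    """Execute (or resume) a campaign and collect the model ensemble.

    Writes the mutated alignments, folds every (set, run) cell that is not
    already complete on disk, and returns the collected
    :class:`ModelEnsemble` plus the manifest.  A failed run is logged under
    ``failures`` and the campaign continues.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "campaign.log.jsonl"
    _log(log_path, "campaign_start", plan=campaign.to_json())

    if backend is None:
        if campaign.backend == "colabfold":
            backend = ColabFoldBackend(models_per_run=campaign.models_per_run)
        else:
            raise ValueError(
                f"no backend instance supplied and backend {campaign.backend!r} "
                "cannot be auto-constructed"
            )

    aln = read_a3m(campaign.base_msa)
    msa_manifest = emit_campaign(
        aln,
        campaign.sets,
        out_dir,
        runs_per_set=campaign.runs_per_set,
        models_per_run=campaign.models_per_run,
    )

    ensemble = ModelEnsemble(models=[])
    failures = []
    runs = []
    for entry in msa_manifest["entries"]:
        set_id = entry["set_id"]
        for k, seed in enumerate(campaign.seeds):
            run_dir = out_dir / "sets" / set_id / f"run{k}"
            expected = [
                run_dir / f"model_{m}.pdb" for m in range(campaign.models_per_run)
            ]
            status = "resumed"
            if not all(p.exists() for p in expected):
                run_dir.mkdir(parents=True, exist_ok=True)
                try:
                    models = backend.fold(entry["a3m"], seed)
                except Exception as exc:  # record and continue with other runs
                    failures.append({"set_id": set_id, "run": k, "error": str(exc)})
                    _log(log_path, "run_failed", set_id=set_id, run=k, error=str(exc))
                    continue
                if len(models) != campaign.models_per_run:
                    failures.append(
                        {
                            "set_id": set_id,
                            "run": k,
                            "error": f"backend returned {len(models)} models",
                        }
                    )
                    continue
                for m, model in enumerate(models):
                    write_model(model, expected[m])
                status = "folded"
            for m, path in enumerate(expected):
                model = read_model(path, plddt_from_bfactor=True,
                                   model_id=f"{set_id}_run{k}_m{m}")
                ensemble.models.append(model)
                ensemble.set_of[model.model_id] = set_id
                ensemble.seed_of[model.model_id] = seed
            runs.append({"set_id": set_id, "run": k, "seed": seed, "status": status})
            _log(log_path, "run_done", set_id=set_id, run=k, seed=seed, status=status)

    manifest = {
        "plan": campaign.to_json(),
        "msas": msa_manifest,
        "runs": runs,
        "failures": failures,
        "expected_total_models": campaign.expected_total_models,
        "collected_models": len(ensemble.models),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    ensemble.validate()
    _log(log_path, "campaign_end", collected=len(ensemble.models))
    return ensemble, manifest


def measure_hinge_angle(model: StructureModel, spec: HingeToySpec) -> float:
    """Opening angle (degrees) of a hinge-toy model: the angle between the
    two arm axes, measured from Cα end-to-end vectors."""
    n, l = spec.n_per_domain, spec.linker_length
    ca = model.ca_coords()
    v_a = ca[n - 1] - ca[0]
    v_b = ca[n + l] - ca[2 * n + l - 1]  # arm B runs antiparallel: tip -> hinge
    cosang = np.dot(v_a, v_b) / (np.linalg.norm(v_a) * np.linalg.norm(v_b))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
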