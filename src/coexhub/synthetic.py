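"""Synthetic RNA-seq count datasets with planted structure.

The generator emulates the two experimental designs the pipeline is built
for, at desk scale, and plants every structure the downstream stages are
supposed to recover:

* **co-expression modules** — groups of genes sharing a module-specific
  latent response curve over the time course (active under treatment
  only), plus per-gene noise, so module members correlate strongly;
* **hub genes** — one designated gene per module carrying the latent
  profile with no gene-specific noise, so it correlates best with every
  member and sits at the module's center in PC space;
* **differentially expressed genes** — gene-specific log2 fold changes
  applied at chosen timepoints (or to chosen mutant strains);
* **a secretome** — secretion scores drawn so planted secreted genes
  score >= 0.5 and all others < 0.5, exercising the inclusive boundary.

Counts are negative binomial with variance ``m + phi * m^2`` — the same
parameterization the differential-expression test assumes, so dispersion
recovery is well-posed.  All randomness flows from one seed; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from coexhub.data_model import (
    DEFAULT_KOG_FOCUS,
    CountMatrix,
    DataModelError,
    GeneAnnotation,
    SampleInfo,
)

TIMECOURSE_TIMEPOINTS = (6.0, 12.0, 15.0, 24.0, 36.0)
MUTANT_TIMEPOINTS = (6.0, 30.0)

_EXTRA_KOGS = (
    "translation, ribosomal structure and biogenesis",
    "transcription",
    "posttranslational modification, protein turnover, chaperones",
    "unassigned",
)


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module with a designated bridge hub.

    All members share the module's latent response curve over the
    timepoints (active under treatment only, scaled by ``amplitude`` in
    log2 units) — that shared curve is what makes the module one cluster
    of expression profiles.  On top of it, the module carries two
    per-sample co-regulation state factors (scale ``substate_sd``), one
    per half of the membership: members of the same half correlate
    strongly, members of opposite halves only through the curve.  The
    first member — the planted hub — carries an equal mixture of both
    state factors instead, so it correlates strongly with *every* member
    and sits between the two halves in the co-expression graph: shortest
    paths between the halves run through it, which is what makes it the
    module's betweenness hub.  ``noise_sd`` is per-gene per-sample noise
    (log2 units).
    """

    size: int
    amplitude: float = 2.8
    noise_sd: float = 0.3
    substate_sd: float = 1.7


@dataclass(frozen=True)
class DEEffect:
    """A planted expression change: ``log2fc`` at one timepoint, applied
    to treatment samples (time-course design) or to one mutant strain."""

    gene_id: str
    timepoint_h: float
    log2fc: float
    strain: str | None = None


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic dataset.

    Defaults emulate the colonization time course: five timepoints (6,
    12, 15, 24, 36 hours post inoculation), two conditions, three
    biological replicates — 30 libraries.  ``design="mutant_2pt"``
    instead produces the two-timepoint mutant comparison (6 and 30 hpi;
    wild type with 10 treatment + 4 control replicates and two mutant
    strains with 4 each — 44 libraries).
    """

    n_genes: int = 300
    design: str = "timecourse_5pt"
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec(10), ModuleSpec(10), ModuleSpec(10),
    )
    n_de_genes: int = 40
    de_log2fc_range: tuple[float, float] = (3.0, 5.0)
    secreted_fraction: float = 0.3
    nb_dispersion: float = 0.05
    base_mean_log: float = float(np.log(200.0))
    base_mean_sdlog: float = 1.0
    depth_sdlog: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("timecourse_5pt", "mutant_2pt"):
            raise DataModelError(f"unknown design {self.design!r}")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise DataModelError("module sizes exceed the number of genes")
        if self.nb_dispersion < 0:
            raise DataModelError("nb_dispersion must be >= 0")
        if not (0.0 <= self.secreted_fraction <= 1.0):
            raise DataModelError("secreted_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted: module membership, hubs, DE events, secretome."""

    modules: dict[int, list[str]]
    hubs: list[str]
    de_effects: list[DEEffect]
    secreted_genes: list[str]
    sscp_genes: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "modules": {str(k): v for k, v in self.modules.items()},
            "hubs": self.hubs,
            "de_effects": [asdict(e) for e in self.de_effects],
            "secreted_genes": self.secreted_genes,
            "sscp_genes": self.sscp_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            modules={int(k): list(v) for k, v in d["modules"].items()},
            hubs=list(d["hubs"]),
            de_effects=[DEEffect(**e) for e in d["de_effects"]],
            secreted_genes=list(d["secreted_genes"]),
            sscp_genes=list(d["sscp_genes"]),
        )


def _design_samples(design: str) -> list[SampleInfo]:
    samples: list[SampleInfo] = []
    if design == "timecourse_5pt":
        for tp in TIMECOURSE_TIMEPOINTS:
            for cond in ("treatment", "control"):
                for rep in (1, 2, 3):
                    sid = f"WT_{cond}_{int(tp):02d}h_r{rep}"
                    samples.append(SampleInfo(sid, cond, "WT", tp, rep))
    else:
        for tp in MUTANT_TIMEPOINTS:
            for rep in range(1, 11):
                samples.append(SampleInfo(f"WT_treatment_{int(tp):02d}h_r{rep}",
                                          "treatment", "WT", tp, rep))
            for rep in range(1, 5):
                samples.append(SampleInfo(f"WT_control_{int(tp):02d}h_r{rep}",
                                          "control", "WT", tp, rep))
            for strain in ("dSm1", "dSir1"):
                for rep in range(1, 5):
                    samples.append(SampleInfo(
                        f"{strain}_treatment_{int(tp):02d}h_r{rep}",
                        "treatment", strain, tp, rep))
    return samples


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate(spec: SyntheticSpec,
             de_effects: Sequence[DEEffect] | None = None,
             ) -> tuple[CountMatrix, dict[str, GeneAnnotation], GroundTruth]:
    """Generate counts, annotation and ground truth for one dataset.

    Gene layout: module genes come first (the first gene of each module is
    its hub), then the planted DE genes, then background genes.  Planted
    secreted genes are the module and DE genes plus enough background
    genes to reach ``secreted_fraction``.  ``de_effects`` overrides the
    automatic DE plan (one effect per DE gene with |log2FC| drawn from
    ``de_log2fc_range`` at a random timepoint; in the mutant design each
    effect targets one of the mutant strains).
    """
    rng = np.random.default_rng(spec.seed)
    samples = _design_samples(spec.design)
    n_s = len(samples)
    genes = _gene_ids(spec.n_genes)
    timepoints = (TIMECOURSE_TIMEPOINTS if spec.design == "timecourse_5pt"
                  else MUTANT_TIMEPOINTS)

    # -- roles ---------------------------------------------------------------
    modules: dict[int, list[str]] = {}
    hubs: list[str] = []
    pos = 0
    for k, m in enumerate(spec.modules):
        modules[k] = genes[pos:pos + m.size]
        hubs.append(genes[pos])  # first member carries the pure latent profile
        pos += m.size
    n_module_genes = pos
    if n_module_genes + spec.n_de_genes > spec.n_genes:
        raise DataModelError("module plus DE genes exceed the number of genes")
    de_gene_ids = genes[pos:pos + spec.n_de_genes]

    if de_effects is None:
        de_effects = []
        lo, hi = spec.de_log2fc_range
        for g in de_gene_ids:
            tp = float(rng.choice(timepoints))
            lfc = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
            strain = (None if spec.design == "timecourse_5pt"
                      else str(rng.choice(["dSm1", "dSir1"])))
            de_effects.append(DEEffect(g, tp, lfc, strain))
    de_effects = list(de_effects)

    planted_secreted = set(g for mod in modules.values() for g in mod)
    planted_secreted |= {e.gene_id for e in de_effects}
    n_secreted_target = int(round(spec.secreted_fraction * spec.n_genes))
    for g in genes:
        if len(planted_secreted) >= n_secreted_target:
            break
        planted_secreted.add(g)
    secreted = sorted(planted_secreted)

    # -- log2 signal matrix --------------------------------------------------
    tp_index = {tp: i for i, tp in enumerate(timepoints)}
    log2_signal = np.zeros((spec.n_genes, n_s))
    gene_index = {g: i for i, g in enumerate(genes)}

    # Module latent curves: centered over timepoints and mutually
    # orthogonalized (Gram-Schmidt) so distinct modules are uncorrelated
    # by construction, then scaled to unit RMS — the peak is then at
    # least 1, so every module responds above the DEG threshold whenever
    # amplitude > lfc_threshold.  At most len(timepoints) - 1 orthogonal
    # centered curves exist; further modules fall back to random curves.
    n_tp = len(timepoints)
    curves = []
    for k in range(len(spec.modules)):
        c = rng.normal(0.0, 1.0, size=n_tp)
        c -= c.mean()
        if k < n_tp - 1:
            for prev in curves[:n_tp - 1]:
                c -= (c @ prev) / (prev @ prev) * prev
        rms = np.sqrt(np.mean(c ** 2))
        curves.append(c / rms if rms > 0 else c)

    treat_mask = np.array([s.condition == "treatment" for s in samples])
    tp_of_sample = np.array([tp_index[s.timepoint_h] for s in samples])
    for k, m in enumerate(spec.modules):
        if m.amplitude == 0:
            continue  # a zero-amplitude module plants no structure at all
        base_curve = m.amplitude * np.where(treat_mask, curves[k][tp_of_sample], 0.0)
        # two per-sample co-regulation states, one per half of the module;
        # the hub (first member) mixes both equally.  The realized state
        # vectors are orthogonalized against each other and the curve so
        # finite-sample chance correlation cannot link the two halves.
        state = rng.normal(0.0, 1.0, size=(2, n_s))
        basis = [base_curve] if np.any(base_curve != 0) else []
        for t in range(2):
            v = state[t] - state[t].mean()
            for b in basis:
                v = v - (v @ b) / (b @ b) * b
            sd = v.std()
            v = v / sd if sd > 0 else v
            state[t] = v
            basis.append(v)
        state = state * m.substate_sd
        half = max(1, (m.size - 1) // 2)
        for row, g in enumerate(modules[k]):
            if row == 0:
                profile = base_curve + (state[0] + state[1]) / np.sqrt(2.0)
            else:
                profile = base_curve + state[0 if row <= half else 1]
            if m.noise_sd > 0:
                profile = profile + rng.normal(0.0, m.noise_sd, size=n_s)
            log2_signal[gene_index[g], :] += profile

    for e in de_effects:
        gi = gene_index[e.gene_id]
        for j, s in enumerate(samples):
            if s.timepoint_h != e.timepoint_h:
                continue
            if e.strain is None:
                hit = s.condition == "treatment"
            else:
                hit = s.strain == e.strain
            if hit:
                log2_signal[gi, j] += e.log2fc

    # -- counts --------------------------------------------------------------
    base = rng.lognormal(spec.base_mean_log, spec.base_mean_sdlog,
                         size=spec.n_genes)
    depth = rng.lognormal(0.0, spec.depth_sdlog, size=n_s)
    mean = base[:, None] * (2.0 ** log2_signal) * depth[None, :]
    phi = spec.nb_dispersion
    if phi == 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mean))

    cm = CountMatrix(gene_ids=genes, samples=samples,
                     counts=counts.astype(np.int64))

    # -- annotation ----------------------------------------------------------
    kog_pool = tuple(DEFAULT_KOG_FOCUS) + _EXTRA_KOGS
    secreted_set = set(secreted)
    annotation: dict[str, GeneAnnotation] = {}
    sscp: list[str] = []
    for g in genes:
        if g in secreted_set:
            score = 0.5 + 0.5 * rng.beta(2.0, 2.0)
            is_sscp = bool(rng.random() < 1.0 / 3.0)
        else:
            score = 0.5 * rng.beta(2.0, 2.0) * 0.999
            is_sscp = False
        if is_sscp:
            sscp.append(g)
        annotation[g] = GeneAnnotation(
            gene_id=g,
            secretion_score=float(min(score, 1.0)),
            kog_category=str(rng.choice(kog_pool)),
            domain_note="SSCP" if is_sscp else "",
            is_sscp=is_sscp,
        )

    truth = GroundTruth(modules=modules, hubs=hubs, de_effects=de_effects,
                        secreted_genes=secreted, sscp_genes=sscp)
    return cm, annotation, truth
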