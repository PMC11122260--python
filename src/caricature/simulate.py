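"""Synthetic cohort generator with a known gene-dosage structure.

Emulates an RMA-style bulk expression study of colorectal tumors and
normal mucosae in which some tumors carry a broad copy-number gain.  For
sample *s* and transcript *t* the log2 expression is

    x_ts = mu_t + beta_t * I(tumor) + gamma_t * log2(c_ts / 2) + eps,
    eps ~ Normal(0, sigma^2)

where ``c_ts`` is the local total copy number implied by the sample's
segments: Selected tumors carry a broad gain of copy number ``c`` over
the target region, Controls and Normals are diploid everywhere.  ``beta``
is the general cancer effect (log2 units), ``gamma`` the dosage exponent
(gamma = 1 is proportional dosage, gamma = 0 dosage-insensitive), so a
dosage-sensitive transcript on the gained region has population
FC2 = (c/2)^gamma — analytically available for every parameter choice.

Sponge partners are generated *from* their lncRNA's realized values,

    m_s = mu_m + beta_m * I(tumor) - kappa * (x_lnc,s - mean(x_lnc)) + eps,

which fixes the sign of the lncRNA–partner correlation: kappa > 0 for a
pri-miRNA partner yields the negative coupling a ceRNA sponge predicts;
marker partners use a positive coupling instead.

Everything is reproducible from one integer seed; per-stage substreams
are derived from it deterministically.  Besides in-memory frames the
generator can write exactly the file dialects the pipeline readers
consume, plus a truth table of each transcript's intended class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Target
from .foldchange import ThresholdConfig, classify_transcript, linear_fold_change
from .genome import ArmDefinition, CopyNumberSegment, arms_by_chromosome


@dataclass(frozen=True)
class TranscriptSpec:
    """Location and generative parameters of one simulated transcript."""

    transcript_id: str
    chrom: str
    start: int
    end: int
    biotype: str  # e.g. lncRNA, pri_mirna, mRNA
    mu: float     # log2 baseline
    beta: float   # log2 cancer effect
    gamma: float  # dosage exponent


@dataclass(frozen=True)
class SpongePair:
    """A partner transcript generated by coupling to a lncRNA.

    ``coupling`` is the magnitude kappa (>= 0); the sign convention
    follows ``partner_kind``: pri-miRNA partners are negatively coupled
    (sponge), markers positively (proliferation).
    """

    lncrna_id: str
    partner_id: str
    partner_kind: str  # pri_mirna | marker
    coupling: float = 0.8
    partner_mu: float = 6.0
    partner_beta: float = 0.0


def toy_genome() -> list[ArmDefinition]:
    """Four two-arm chromosomes named after the study's target regions."""
    arms = []
    for chrom in ("7", "8", "13", "20"):
        arms.append(ArmDefinition(chrom, "p", 0, 40_000_000))
        arms.append(ArmDefinition(chrom, "q", 40_000_000, 100_000_000))
    return arms


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort sizes, genome, dosage model and noise for one simulation.

    Defaults mirror the scale of an HTA-style colorectal study: 26
    normal mucosae and 46 tumors (23 with the target gain, 23 without),
    a trisomy (c = 3) of the 20q target arm, log2 noise SD 0.3, and one
    negatively coupled pri-miRNA plus one positively coupled marker
    partner for the first dosage-sensitive lncRNA on the gained arm.
    """

    n_normal: int = 26
    n_selected: int = 23
    n_control: int = 23
    genome: tuple[ArmDefinition, ...] = field(default_factory=lambda: tuple(toy_genome()))
    target_chrom: str = "20"
    target_scope: str = "q"  # p, q or w
    copy_number: int = 3
    sigma: float = 0.3
    transcripts: tuple[TranscriptSpec, ...] | None = None  # None -> default layout
    sponge_pairs: tuple[SpongePair, ...] | None = None     # None -> default pairs
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_normal, self.n_selected, self.n_control) < 0:
            raise ValueError("sample counts must be >= 0")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.target_scope not in ("p", "q", "w"):
            raise ValueError("target_scope must be p, q or w")

    @property
    def target(self) -> Target:
        scopes = {"q", "w"} if self.target_scope in ("q", "p") else {"p", "q", "w"}
        if self.target_scope == "p":
            scopes = {"p", "w"}
        return Target(self.target_chrom, frozenset(scopes), "gain")

    def target_region(self) -> tuple[str, int, int]:
        """(chrom, start, end) of the gained interval."""
        chrom_arms = arms_by_chromosome(self.genome).get(self.target_chrom)
        if not chrom_arms:
            raise ValueError(f"target chromosome {self.target_chrom!r} not in genome")
        if self.target_scope == "w":
            return (
                self.target_chrom,
                min(a.start for a in chrom_arms),
                max(a.end for a in chrom_arms),
            )
        for a in chrom_arms:
            if a.arm == self.target_scope:
                return (self.target_chrom, a.start, a.end)
        raise ValueError(
            f"arm {self.target_chrom}{self.target_scope} not in genome"
        )


def expected_fc2(c: float, gamma: float) -> float:
    """Population FC2 of a dosage-sensitive transcript: (c/2) ** gamma."""
    if c <= 0:
        raise ValueError(f"copy number must be > 0, got {c}")
    return (c / 2.0) ** gamma


def default_transcripts(config: SyntheticConfig) -> list[TranscriptSpec]:
    """Deterministic 200-transcript layout over the toy genome.

    Per arm, 25 evenly spaced transcripts.  The target arm carries 10
    dosage-sensitive lncRNAs (beta = 1, gamma = 1 — the caricature
    candidates), 5 cancer-only transcripts (beta = 1, gamma = 0) and 10
    nulls; every other arm carries 5 cancer-only transcripts and 20
    nulls.  Baselines are fixed at 6.0 log2 units, a mid-range RMA value.
    """
    chrom_region = config.target_region()
    specs: list[TranscriptSpec] = []
    for arm in config.genome:
        step = arm.length_bp // 26
        on_target = (
            arm.chromosome == chrom_region[0]
            and arm.start >= chrom_region[1]
            and arm.end <= chrom_region[2]
        )
        for i in range(25):
            start = arm.start + (i + 1) * step
            end = start + min(10_000, step - 1)
            if on_target:
                if i < 10:
                    beta, gamma, biotype = 1.0, 1.0, "lncRNA"
                elif i < 15:
                    beta, gamma, biotype = 1.0, 0.0, "lncRNA"
                else:
                    beta, gamma, biotype = 0.0, 0.0, "mRNA"
            else:
                if i < 5:
                    beta, gamma, biotype = 1.0, 0.0, "mRNA"
                else:
                    beta, gamma, biotype = 0.0, 0.0, "mRNA"
            specs.append(
                TranscriptSpec(
                    f"T_{arm.chromosome}{arm.arm}_{i:02d}",
                    arm.chromosome,
                    start,
                    end,
                    biotype,
                    6.0,
                    beta,
                    gamma,
                )
            )
    return specs


def default_sponge_pairs(transcripts: list[TranscriptSpec]) -> list[SpongePair]:
    """One pri-miRNA and one marker partner for the first caricature lncRNA."""
    lnc = next(
        (t for t in transcripts if t.gamma > 0 and t.beta > 0 and t.biotype == "lncRNA"),
        None,
    )
    if lnc is None:
        return []
    return [
        SpongePair(lnc.transcript_id, "PRIMIR_01", "pri_mirna", 0.8, 6.0, -0.5),
        SpongePair(lnc.transcript_id, "MARKER_01", "marker", 0.8, 7.0, 0.5),
    ]


@dataclass
class SyntheticCohort:
    """All artifacts of one simulation, in memory."""

    config: SyntheticConfig
    expression: pd.DataFrame        # transcripts x samples, log2
    segments: list[CopyNumberSegment]
    sample_sheet: pd.DataFrame      # sample_id, tissue
    annotation: pd.DataFrame        # indexed by transcript_id
    truth: pd.DataFrame             # indexed by transcript_id
    pairs: pd.DataFrame             # lncrna_id, partner_id, partner_kind

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every input file the pipeline readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "segments": outdir / "segments.tsv",
            "samples": outdir / "samples.tsv",
            "cytobands": outdir / "cytobands.tsv",
            "annotation": outdir / "annotation.tsv",
            "truth": outdir / "truth.tsv",
            "pairs": outdir / "pairs.tsv",
        }
        self.expression.to_csv(paths["expression"], sep="\t", index_label="transcript_id")
        seg_rows = [
            {
                "sample_id": s.sample_id,
                "chrom": s.chromosome,
                "start": s.start + 1,  # written 1-based inclusive
                "end": s.end,
                "cn_state": s.cn_state,
                "minor_cn": "" if s.minor_cn is None else s.minor_cn,
            }
            for s in self.segments
        ]
        pd.DataFrame(
            seg_rows,
            columns=["sample_id", "chrom", "start", "end", "cn_state", "minor_cn"],
        ).to_csv(paths["segments"], sep="\t", index=False)
        self.sample_sheet.to_csv(paths["samples"], sep="\t", index=False)
        with open(paths["cytobands"], "w") as fh:
            for arm in self.config.genome:
                fh.write(
                    f"chr{arm.chromosome}\t{arm.start}\t{arm.end}\t"
                    f"{arm.arm}11\tgneg\n"
                )
        self.annotation.to_csv(paths["annotation"], sep="\t", index_label="transcript_id")
        self.truth.to_csv(paths["truth"], sep="\t", index_label="transcript_id")
        self.pairs.to_csv(paths["pairs"], sep="\t", index=False)
        return paths


def _population_group_means(
    spec: TranscriptSpec, config: SyntheticConfig, region: tuple[str, int, int]
) -> tuple[float, float, float]:
    """Noise-free (normal, control, selected) log2 means of one transcript."""
    inside = (
        spec.chrom == region[0]
        and spec.start >= region[1]
        and spec.end <= region[2]
    )
    dosage = spec.gamma * np.log2(config.copy_number / 2.0) if inside else 0.0
    return spec.mu, spec.mu + spec.beta, spec.mu + spec.beta + dosage


def simulate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Draw one cohort: expression, segments, sheet, truth, pairs."""
    config = config or SyntheticConfig()
    transcripts = (
        list(config.transcripts)
        if config.transcripts is not None
        else default_transcripts(config)
    )
    region = config.target_region()
    chrom_arms = arms_by_chromosome(config.genome)
    for t in transcripts:
        arms = chrom_arms.get(t.chrom)
        if arms is None or t.start < min(a.start for a in arms) or t.end > max(
            a.end for a in arms
        ):
            raise ValueError(
                f"transcript {t.transcript_id} at {t.chrom}:{t.start}-{t.end} "
                "lies outside the genome"
            )
    pairs = (
        list(config.sponge_pairs)
        if config.sponge_pairs is not None
        else default_sponge_pairs(transcripts)
    )

    ss = np.random.SeedSequence(config.seed)
    rng_expr, rng_sponge = (np.random.default_rng(s) for s in ss.spawn(2))

    normal_ids = [f"N{i + 1:03d}" for i in range(config.n_normal)]
    selected_ids = [f"S{i + 1:03d}" for i in range(config.n_selected)]
    control_ids = [f"C{i + 1:03d}" for i in range(config.n_control)]
    samples = normal_ids + selected_ids + control_ids
    is_tumor = np.array([0] * config.n_normal + [1] * (config.n_selected + config.n_control))
    is_selected = np.array(
        [0] * config.n_normal + [1] * config.n_selected + [0] * config.n_control
    )

    mu = np.array([t.mu for t in transcripts])
    beta = np.array([t.beta for t in transcripts])
    gamma = np.array([t.gamma for t in transcripts])
    inside = np.array(
        [
            t.chrom == region[0] and t.start >= region[1] and t.end <= region[2]
            for t in transcripts
        ]
    )
    dosage_shift = np.log2(config.copy_number / 2.0) if config.copy_number > 0 else 0.0

    # copy number per transcript/sample: gained only on target region of Selected
    log2_dose = (
        gamma[:, None] * inside[:, None] * is_selected[None, :] * dosage_shift
    )
    x = (
        mu[:, None]
        + beta[:, None] * is_tumor[None, :]
        + log2_dose
        + rng_expr.normal(0.0, config.sigma, size=(len(transcripts), len(samples)))
    )
    expression = pd.DataFrame(
        x, index=[t.transcript_id for t in transcripts], columns=samples
    )

    # sponge/marker partners appended, coupled to realized lncRNA values
    partner_rows = {}
    for pair in pairs:
        if pair.lncrna_id not in expression.index:
            raise ValueError(f"sponge lncRNA {pair.lncrna_id!r} not among transcripts")
        lnc = expression.loc[pair.lncrna_id].to_numpy()
        sign = -1.0 if pair.partner_kind == "pri_mirna" else 1.0
        partner_rows[pair.partner_id] = (
            pair.partner_mu
            + pair.partner_beta * is_tumor
            + sign * pair.coupling * (lnc - lnc.mean())
            + rng_sponge.normal(0.0, config.sigma, size=len(samples))
        )
    if partner_rows:
        expression = pd.concat(
            [expression, pd.DataFrame(partner_rows, index=samples).T]
        )

    # segments: Selected tumors carry the broad gain; everyone else is diploid
    cn_state = int(np.clip(config.copy_number - 2, -2, 2))
    segments = [
        CopyNumberSegment(sid, region[0], region[1], region[2], cn_state)
        for sid in selected_ids
    ]

    sample_sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "tissue": ["normal"] * config.n_normal
            + ["tumor"] * (config.n_selected + config.n_control),
        }
    )

    annotation = pd.DataFrame(
        {
            "chrom": [t.chrom for t in transcripts],
            "start": [t.start for t in transcripts],
            "end": [t.end for t in transcripts],
            "strand": ["+"] * len(transcripts),
            "biotype": [t.biotype for t in transcripts],
        },
        index=[t.transcript_id for t in transcripts],
    )
    partner_region_start = 0
    for pair in pairs:
        annotation.loc[pair.partner_id] = {
            "chrom": "7",
            "start": partner_region_start,
            "end": partner_region_start + 1_000,
            "strand": "+",
            "biotype": pair.partner_kind,
        }
        partner_region_start += 10_000

    truth = _truth_table(transcripts, pairs, config, region)
    pairs_df = pd.DataFrame(
        [
            {
                "lncrna_id": p.lncrna_id,
                "partner_id": p.partner_id,
                "partner_kind": p.partner_kind,
            }
            for p in pairs
        ],
        columns=["lncrna_id", "partner_id", "partner_kind"],
    )
    return SyntheticCohort(
        config, expression, segments, sample_sheet, annotation, truth, pairs_df
    )


def _truth_table(
    transcripts: list[TranscriptSpec],
    pairs: list[SpongePair],
    config: SyntheticConfig,
    region: tuple[str, int, int],
) -> pd.DataFrame:
    """Intended FC2/FC3/FC4 and class of every output row, from closed forms.

    Ordinary transcripts follow the generative equation directly.  Sponge
    partners are affine in their lncRNA, so their noise-free group means
    follow from the lncRNA's — the coupling is centered on the cohort
    mean, which shifts every group by the same constant and cancels in
    the fold changes except through the tumor/selection structure.
    """
    n_n, n_s, n_c = config.n_normal, config.n_selected, config.n_control
    total = n_n + n_s + n_c
    rows = {}
    pop_means = {}
    for t in transcripts:
        m_norm, m_ctrl, m_sel = _population_group_means(t, config, region)
        pop_means[t.transcript_id] = (m_norm, m_ctrl, m_sel)
        rows[t.transcript_id] = (m_norm, m_ctrl, m_sel)
    for p in pairs:
        ln, lc, ls = pop_means[p.lncrna_id]
        grand = (n_n * ln + n_c * lc + n_s * ls) / total if total else ln
        sign = -1.0 if p.partner_kind == "pri_mirna" else 1.0
        rows[p.partner_id] = (
            p.partner_mu + sign * p.coupling * (ln - grand),
            p.partner_mu + p.partner_beta + sign * p.coupling * (lc - grand),
            p.partner_mu + p.partner_beta + sign * p.coupling * (ls - grand),
        )

    records = []
    for tid, (m_norm, m_ctrl, m_sel) in rows.items():
        fc2 = linear_fold_change(m_sel, m_ctrl)
        fc3 = linear_fold_change(m_ctrl, m_norm)
        fc4 = linear_fold_change(m_sel, m_norm)
        records.append(
            {
                "transcript_id": tid,
                "fc2": fc2,
                "fc3": fc3,
                "fc4": fc4,
                "class_label": classify_transcript(fc2, fc3, fc4, config.thresholds),
            }
        )
    return pd.DataFrame(records).set_index("transcript_id")


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
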