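"""Ground-truthed synthetic inputs emulating the study design.

The generator builds a toy organism end to end: genes with exon structure
and shared-exon isoforms (the isogroup/isotig model a pyrosequencing
transcriptome assembler produces), medium-length reads with substitution and
homopolymer-indel errors plus a contaminant fraction, a two-channel genomic
hybridization whose background rises with GC content above a threshold, and
a two-protocol expression experiment in which the ddNTP-truncated channel
decays much faster with distance from the transcript 3′ end than the regular
oligo-dT channel.  Every simulated probe carries a truth row (genomic
presence, true transcript, true 3′ distance, contaminant origin) so
parameter-recovery tests can score the pipeline against ground truth.

All randomness flows from one seed; each stage draws from its own fixed
substream, so stages are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import align, design
from .core import SequenceRecord, TranscriptomeAssembly, assign_ids

LN2 = math.log(2)

_STAGE = {
    "transcriptome": 1,
    "reads": 2,
    "controls": 3,
    "acgh": 4,
    "age": 5,
    "expr": 6,
}

PRESENCE = ("target_only", "reference_only", "both", "neither")


@dataclass
class SimConfig:
    """Generator parameters; defaults are the simulated study conditions."""

    seed: int = 42
    # transcriptome structure
    n_genes: int = 50
    isoform_probs: tuple[float, float, float] = (0.86, 0.10, 0.04)
    exons_per_gene: tuple[int, int] = (1, 6)
    transcript_len: tuple[int, int] = (400, 3000)
    min_exon_len: int = 80
    gc_mean: float = 0.40
    gc_sd: float = 0.07
    singleton_gene_fraction: float = 0.30
    conserved_fraction: float = 0.10
    conserved_divergence: float = 0.02
    intergenic_len: int = 200
    contaminant_genome_len: int = 20_000
    contaminant_gc: float = 0.50
    # reads
    n_reads: int = 300
    read_len_mean: float = 330.0
    read_len_sd: float = 80.0
    read_len_bounds: tuple[int, int] = (60, 600)
    per_base_error: float = 0.001
    homopolymer_indel_rate: float = 0.01  # per run, scaled by (run - 2)
    contaminant_fraction: float = 0.05
    # hybridization signal model (log2 scale)
    base_high: float = 12.0
    acgh_background: float = 6.0
    gc_ramp_threshold: float = 0.45
    gc_ramp_slope: float = 10.0  # log2 units per unit GC above threshold
    age_background: float = 3.0
    decay_reg: float = 1500.0  # bp per e-folding, regular amplification
    decay_res: float = 300.0  # bp per e-folding, ddNTP-restricted
    expr_mu: float = 8.0
    expr_sigma: float = 1.5
    noise_sd: float = 0.3
    # controls
    n_neg_controls: int = 100
    n_pos_controls: int = 50
    probe_len: int = 60
    id_prefix: str = "Sim"

    def __post_init__(self) -> None:
        if abs(sum(self.isoform_probs) - 1.0) > 1e-9:
            raise ValueError("isoform probabilities must sum to 1")
        for name in ("decay_reg", "decay_res", "read_len_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.transcript_len
        if lo < self.min_exon_len or hi < lo:
            raise ValueError("infeasible transcript length constraints")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGE[stage]])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTranscriptome:
    """Ground-truth transcriptome: genomes, assembly and provenance maps."""

    target_genome: SequenceRecord
    reference_genome: SequenceRecord
    assembly: TranscriptomeAssembly
    transcripts: dict[str, str]  # raw transcript id -> sequence
    tx_gene: dict[str, str]  # raw transcript id -> gene id
    gene_locus: dict[str, str]  # gene id -> genomic locus sequence
    reference_copy: dict[str, str]  # conserved gene id -> diverged copy
    isotig_of_tx: dict[str, str]  # raw transcript id -> isotig id
    singleton_origin: dict[str, tuple[str, int]]  # singleton id -> (tx, start)
    contaminant_genome: str
    contaminant_singletons: list[str] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def simulate_transcriptome(cfg: SimConfig) -> SimTranscriptome:
    """Genes → exons → isoforms, genomes, and the assembled ground truth.

    Isoforms of a gene share exons (isoform k > 1 skips one exon), giving the
    isogroup structure.  A configurable fraction of genes is left
    "unassembled": a read-sized 3′ fragment of each becomes a singleton
    instead of an isotig.  The target genome concatenates every gene's exons
    (with intergenic spacers); the reference genome is independent random
    sequence except for a conserved fraction of loci copied in with slight
    divergence.
    """
    rng = cfg.rng("transcriptome")
    n_iso_choices = np.array([1, 2, 3])

    transcripts: dict[str, str] = {}
    tx_gene: dict[str, str] = {}
    gene_locus: dict[str, str] = {}
    gene_isos: dict[str, list[str]] = {}
    contig_membership: dict[str, list[str]] = {}
    gene_exons: dict[str, list[str]] = {}
    conserved: set[str] = set()

    for g in range(cfg.n_genes):
        gene = f"G{g + 1:04d}"
        n_iso = int(rng.choice(n_iso_choices, p=list(cfg.isoform_probs)))
        lo, hi = cfg.exons_per_gene
        n_ex = int(rng.integers(lo, hi + 1))
        n_ex = max(n_ex, n_iso)  # enough exons to skip distinct ones
        tx_len = int(rng.integers(cfg.transcript_len[0], cfg.transcript_len[1] + 1))
        w = rng.random(n_ex) + 0.5
        ex_lens = np.maximum(
            cfg.min_exon_len, np.round(tx_len * w / w.sum()).astype(int)
        )
        gc = float(np.clip(rng.normal(cfg.gc_mean, cfg.gc_sd), 0.25, 0.65))
        exons = [_random_seq(rng, int(n), gc) for n in ex_lens]
        gene_exons[gene] = exons
        gene_locus[gene] = "".join(exons)
        if rng.random() < cfg.conserved_fraction:
            conserved.add(gene)

        skip_order = rng.permutation(n_ex)
        isos = []
        for k in range(n_iso):
            if k == 0:
                members = list(range(n_ex))
            else:
                members = [i for i in range(n_ex) if i != skip_order[k - 1]]
                if not members:  # single-exon gene cannot skip
                    continue
            tx_id = f"{gene}.{k + 1}"
            transcripts[tx_id] = "".join(exons[i] for i in members)
            tx_gene[tx_id] = gene
            contig_membership[tx_id] = [f"{gene}.e{i + 1}" for i in members]
            isos.append(tx_id)
        gene_isos[gene] = isos

    # genomes
    rng_g = rng  # continue the same substream deterministically
    spacers = [
        _random_seq(rng_g, cfg.intergenic_len, 0.40) for _ in range(cfg.n_genes + 1)
    ]
    target = spacers[0] + "".join(
        gene_locus[f"G{g + 1:04d}"] + spacers[g + 1] for g in range(cfg.n_genes)
    )
    reference_copy = {
        g: _diverge(rng_g, gene_locus[g], cfg.conserved_divergence)
        for g in sorted(conserved)
    }
    ref_random_len = max(len(target) - sum(len(s) for s in reference_copy.values()), 1000)
    reference = _random_seq(rng_g, ref_random_len, 0.40) + "".join(
        reference_copy[g] for g in sorted(reference_copy)
    )
    contaminant = _random_seq(rng_g, cfg.contaminant_genome_len, cfg.contaminant_gc)

    # which genes assembled; unassembled genes yield singleton fragments
    genes = sorted(gene_isos)
    unassembled = {
        g for g in genes if rng_g.random() < cfg.singleton_gene_fraction
    }
    isotigs: dict[str, SequenceRecord] = {}
    isogroups: dict[str, list[str]] = {}
    isotig_contigs: dict[str, list[str]] = {}
    singletons: dict[str, SequenceRecord] = {}
    singleton_origin: dict[str, tuple[str, int]] = {}

    for g in genes:
        if g in unassembled:
            tx_id = gene_isos[g][0]
            seq = transcripts[tx_id]
            frag_len = int(
                np.clip(rng_g.normal(cfg.read_len_mean, cfg.read_len_sd),
                        cfg.read_len_bounds[0], cfg.read_len_bounds[1])
            )
            frag_len = min(frag_len, len(seq))
            start = len(seq) - frag_len  # 3'-biased fragment survives cDNA prep
            sid = f"S_{tx_id}"
            singletons[sid] = SequenceRecord(sid, seq[start:], kind="singleton")
            singleton_origin[sid] = (tx_id, start)
        else:
            isogroups[g] = []
            for tx_id in gene_isos[g]:
                isotigs[tx_id] = SequenceRecord(
                    tx_id, transcripts[tx_id], kind="isotig"
                )
                isogroups[g].append(tx_id)
                isotig_contigs[tx_id] = contig_membership[tx_id]

    n_cont_sing = int(round(cfg.contaminant_fraction * max(len(unassembled), 1)))
    contaminant_singletons = []
    for i in range(n_cont_sing):
        frag_len = int(
            np.clip(rng_g.normal(cfg.read_len_mean, cfg.read_len_sd),
                    cfg.read_len_bounds[0], cfg.read_len_bounds[1])
        )
        start = int(rng_g.integers(0, len(contaminant) - frag_len + 1))
        sid = f"S_cont{i + 1}"
        singletons[sid] = SequenceRecord(
            sid, contaminant[start : start + frag_len], kind="singleton"
        )
        contaminant_singletons.append(sid)

    assembly = TranscriptomeAssembly(
        isogroups=isogroups,
        isotigs=isotigs,
        singletons=singletons,
        contig_membership=isotig_contigs,
    )
    assembly, id_map = assign_ids(assembly, cfg.id_prefix)
    isotig_of_tx = {tx: id_map[tx] for tx in isotigs}
    singleton_origin = {
        id_map[sid]: origin for sid, origin in singleton_origin.items()
    }
    contaminant_singletons = [id_map[s] for s in contaminant_singletons]

    return SimTranscriptome(
        target_genome=SequenceRecord("target_genome", target, kind="genome"),
        reference_genome=SequenceRecord("reference_genome", reference, kind="genome"),
        assembly=assembly,
        transcripts=transcripts,
        tx_gene=tx_gene,
        gene_locus=gene_locus,
        reference_copy=reference_copy,
        isotig_of_tx=isotig_of_tx,
        singleton_origin=singleton_origin,
        contaminant_genome=contaminant,
        contaminant_singletons=contaminant_singletons,
    )


def _apply_errors(rng: np.random.Generator, seq: str, cfg: SimConfig) -> str:
    """Substitutions at the per-base rate plus length-scaled homopolymer
    indels (the dominant pyrosequencing error mode)."""
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(out)) < cfg.per_base_error):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    if cfg.homopolymer_indel_rate > 0:
        s = "".join(out)
        edits: list[tuple[int, int, str]] = []  # (pos, del, ins)
        i = 0
        while i < len(s):
            j = i
            while j < len(s) and s[j] == s[i]:
                j += 1
            run = j - i
            if run >= 3 and rng.random() < cfg.homopolymer_indel_rate * (run - 2):
                if rng.random() < 0.5:
                    edits.append((i, 1, ""))  # deletion
                else:
                    edits.append((i, 0, s[i]))  # insertion
            i = j
        for pos, ndel, ins in reversed(edits):
            s = s[:pos] + ins + s[pos + ndel :]
        return s
    return "".join(out)


def simulate_reads(
    sim: SimTranscriptome, cfg: SimConfig
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Sample error-bearing reads from transcripts plus contaminant reads.

    Returns the reads and a truth table (read_id, tx_id, tx_start,
    is_contaminant); contaminant reads come from an unrelated random genome
    and carry an empty tx_id.
    """
    rng = cfg.rng("reads")
    tx_ids = sorted(sim.transcripts)
    n_cont = int(round(cfg.n_reads * cfg.contaminant_fraction))
    n_real = cfg.n_reads - n_cont

    reads: list[SequenceRecord] = []
    truth_rows: list[dict] = []

    def draw_len(limit: int) -> int:
        lo, hi = cfg.read_len_bounds
        val = int(np.clip(rng.normal(cfg.read_len_mean, cfg.read_len_sd), lo, hi))
        return min(val, limit)

    for i in range(n_real):
        tx = tx_ids[int(rng.integers(0, len(tx_ids)))]
        seq = sim.transcripts[tx]
        length = draw_len(len(seq))
        start = int(rng.integers(0, len(seq) - length + 1))
        raw = seq[start : start + length]
        rid = f"R{i + 1:06d}"
        reads.append(SequenceRecord(rid, _apply_errors(rng, raw, cfg), kind="read"))
        truth_rows.append(
            {"read_id": rid, "tx_id": tx, "tx_start": start, "is_contaminant": False}
        )
    for i in range(n_cont):
        length = draw_len(len(sim.contaminant_genome))
        start = int(rng.integers(0, len(sim.contaminant_genome) - length + 1))
        rid = f"R{n_real + i + 1:06d}"
        reads.append(
            SequenceRecord(
                rid,
                _apply_errors(
                    rng, sim.contaminant_genome[start : start + length], cfg
                ),
                kind="read",
            )
        )
        truth_rows.append(
            {"read_id": rid, "tx_id": "", "tx_start": -1, "is_contaminant": True}
        )
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "tx_id", "tx_start", "is_contaminant"]
    )
    return reads, truth


def make_control_probes(
    sim: SimTranscriptome, cfg: SimConfig
) -> tuple[list[design.Probe], pd.DataFrame]:
    """Negative controls (random oligos with a broad GC spread, present in no
    genome) and positive controls (windows drawn from the target genome's
    gene loci, so their genomic presence is guaranteed)."""
    rng = cfg.rng("controls")
    probes: list[design.Probe] = []
    rows: list[dict] = []
    for i in range(cfg.n_neg_controls):
        gc = float(rng.uniform(0.20, 0.70))
        seq = _random_seq(rng, cfg.probe_len, gc)
        pid = f"NEG{i + 1:05d}"
        probes.append(
            design.Probe(pid, pid, 0, "+", seq, design.gc_content(seq),
                         origin="negative_control")
        )
        rows.append(_truth_row(pid, "neither", None, None, False))
    genes = sorted(sim.gene_locus)
    scheme = align.ScoringScheme()
    for i in range(cfg.n_pos_controls):
        gene = genes[int(rng.integers(0, len(genes)))]
        locus = sim.gene_locus[gene]
        start = int(rng.integers(0, len(locus) - cfg.probe_len + 1))
        seq = locus[start : start + cfg.probe_len]
        pid = f"POS{i + 1:05d}"
        presence = "target_only"
        if gene in sim.reference_copy:
            hit = align.local_align(seq, sim.reference_copy[gene], scheme)
            if align.bit_score(hit.raw_score, scheme) > 80:
                presence = "both"
        probes.append(
            design.Probe(pid, pid, start, "+", seq, design.gc_content(seq),
                         origin="positive_control")
        )
        rows.append(_truth_row(pid, presence, None, None, False))
    return probes, pd.DataFrame(rows, columns=_TRUTH_COLS)


_TRUTH_COLS = [
    "probe_id",
    "genomic_presence",
    "true_transcript",
    "true_3prime_distance",
    "is_contaminant_origin",
]


def _truth_row(pid, presence, tx, d, cont) -> dict:
    return {
        "probe_id": pid,
        "genomic_presence": presence,
        "true_transcript": tx,
        "true_3prime_distance": d,
        "is_contaminant_origin": cont,
    }


def probe_truth(
    probes: list[design.Probe],
    sim: SimTranscriptome,
    read_truth: pd.DataFrame,
    cfg: SimConfig,
    scheme: align.ScoringScheme | None = None,
    threshold: float = 80.0,
) -> pd.DataFrame:
    """Truth rows for read-derived probes.

    Genomic presence in the target is decided by aligning the probe against
    its source gene's locus (read errors or junction-spanning windows can
    break it); presence in the reference likewise against the conserved copy
    when one exists.  Contaminant-origin probes are absent from both genomes
    by construction — an unrelated random 60-mer cannot reach the bit
    threshold against either, so no genome scan is performed for them.
    """
    scheme = scheme or align.ScoringScheme()
    rt = read_truth.set_index("read_id")
    rows = []
    for p in probes:
        if p.origin in ("negative_control", "positive_control"):
            continue
        info = rt.loc[p.source_id]
        if bool(info["is_contaminant"]):
            rows.append(_truth_row(p.probe_id, "neither", None, None, True))
            continue
        tx = info["tx_id"]
        pos = int(info["tx_start"]) + p.start  # indels shift this by O(1) bp
        tx_len = len(sim.transcripts[tx])
        d = max(0, tx_len - (pos + len(p.sequence)))
        gene = sim.tx_gene[tx]
        hit = align.local_align(p.sequence, sim.gene_locus[gene], scheme)
        in_target = align.bit_score(hit.raw_score, scheme) > threshold
        in_ref = False
        if gene in sim.reference_copy:
            rhit = align.local_align(p.sequence, sim.reference_copy[gene], scheme)
            in_ref = align.bit_score(rhit.raw_score, scheme) > threshold
        presence = {
            (True, True): "both",
            (True, False): "target_only",
            (False, True): "reference_only",
            (False, False): "neither",
        }[(in_target, in_ref)]
        rows.append(_truth_row(p.probe_id, presence, tx, d, False))
    return pd.DataFrame(rows, columns=_TRUTH_COLS)


def genomic_presence(
    probe_seq: str,
    target_genome: str,
    reference_genome: str,
    scheme: align.ScoringScheme | None = None,
    threshold: float = 80.0,
) -> str:
    """Presence category by direct alignment against both full genomes
    (slow path; used when no provenance truth is available)."""
    scheme = scheme or align.ScoringScheme()

    def present(genome: str) -> bool:
        hit = align.local_align(probe_seq, genome, scheme)
        return align.bit_score(hit.raw_score, scheme) > threshold

    in_t, in_r = present(target_genome), present(reference_genome)
    return {
        (True, True): "both",
        (True, False): "target_only",
        (False, True): "reference_only",
        (False, False): "neither",
    }[(in_t, in_r)]


def simulate_acgh(
    probes: list[design.Probe],
    truth: pd.DataFrame,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Two-channel genomic-hybridization intensities.

    A probe present in a genome reads out at ``base_high`` in that channel;
    an absent probe reads out at the GC-dependent background
    b0 + slope·max(0, gc − threshold) — background rises with GC above the
    threshold.  Gaussian noise (sd ``noise_sd``) on the log2 scale.
    """
    rng = cfg.rng("acgh")
    presence = truth.set_index("probe_id")["genomic_presence"]
    rows = []
    for p in probes:
        bg = cfg.acgh_background + cfg.gc_ramp_slope * max(
            0.0, p.gc - cfg.gc_ramp_threshold
        )
        pres = presence[p.probe_id]
        t_mean = cfg.base_high if pres in ("target_only", "both") else bg
        r_mean = cfg.base_high if pres in ("reference_only", "both") else bg
        noise = rng.normal(0.0, cfg.noise_sd, size=2) if cfg.noise_sd else (0.0, 0.0)
        rows.append(
            {
                "probe_id": p.probe_id,
                "t_log2": t_mean + noise[0],
                "r_log2": r_mean + noise[1],
            }
        )
    return pd.DataFrame(rows, columns=["probe_id", "t_log2", "r_log2"])


def transcript_expression(sim: SimTranscriptome, cfg: SimConfig) -> dict[str, float]:
    """Per-transcript log2 expression levels (normal on the log2 scale)."""
    rng = cfg.rng("expr")
    return {
        tx: float(rng.normal(cfg.expr_mu, cfg.expr_sigma))
        for tx in sorted(sim.transcripts)
    }


def simulate_age(
    probes: list[design.Probe],
    truth: pd.DataFrame,
    sim: SimTranscriptome,
    cfg: SimConfig,
    expression: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Two-protocol expression intensities.

    For a probe at true 3′ distance d on an expressed transcript:
    reg = expr − d / (decay_reg·ln 2) and res = expr − d / (decay_res·ln 2)
    (each floored at the array background), so the restricted channel loses
    one log2 unit every decay_res·ln2 bp from the 3′ end.  Contaminant-origin
    probes and controls read out at background.  Gaussian noise on top.
    """
    rng = cfg.rng("age")
    expression = expression or transcript_expression(sim, cfg)
    tinfo = truth.set_index("probe_id")
    rows = []
    for p in probes:
        tx = tinfo.loc[p.probe_id, "true_transcript"] if p.probe_id in tinfo.index else None
        if tx is not None and not (isinstance(tx, float) and math.isnan(tx)) and tx:
            expr = expression[tx]
            d = float(tinfo.loc[p.probe_id, "true_3prime_distance"])
            reg_mean = max(expr - d / (cfg.decay_reg * LN2), cfg.age_background)
            res_mean = max(expr - d / (cfg.decay_res * LN2), cfg.age_background)
        else:
            reg_mean = res_mean = cfg.age_background
        noise = rng.normal(0.0, cfg.noise_sd, size=2) if cfg.noise_sd else (0.0, 0.0)
        rows.append(
            {
                "probe_id": p.probe_id,
                "reg_log2": reg_mean + noise[0],
                "res_log2": res_mean + noise[1],
            }
        )
    return pd.DataFrame(rows, columns=["probe_id", "reg_log2", "res_log2"])


@dataclass
class SimBundle:
    """Everything one synthetic run produces, ready for the pipeline."""

    cfg: SimConfig
    sim: SimTranscriptome
    reads: list[SequenceRecord]
    read_truth: pd.DataFrame
    probes: list[design.Probe]  # designed library probes + controls
    truth: pd.DataFrame  # per-probe truth table
    acgh: pd.DataFrame
    age: pd.DataFrame
    discard_log: design.DiscardLog


def simulate_all(
    cfg: SimConfig,
    probes_per_read: int = 2,
    design_constraints: design.DesignConstraints | None = None,
) -> SimBundle:
    """Full generator: transcriptome → reads → probe design → intensities."""
    dc = design_constraints or design.DesignConstraints(probe_len=cfg.probe_len)
    sim = simulate_transcriptome(cfg)
    reads, read_truth = simulate_reads(sim, cfg)

    log = design.DiscardLog()
    sources = design.eligible_sources(reads, dc)
    for r in reads:
        if r not in sources:
            reason = "has_n" if (dc.forbid_n and r.has_n) else "short_source"
            log.add(r.id, r.id, reason)
    lib = design.design_candidate_probes(
        sources, dc, per_source=probes_per_read, discard_log=log
    )
    # group reads by true gene so shared within-gene sequence is not treated
    # as cross-hybridization
    rt = read_truth.set_index("read_id")
    gene_of_read = {
        rid: (sim.tx_gene[row.tx_id] if row.tx_id else f"cont:{rid}")
        for rid, row in rt.iterrows()
    }
    lib, _ = design.cross_hyb_screen(
        lib, isogroup_of_source=gene_of_read, discard_log=log
    )

    lib_truth = probe_truth(lib, sim, read_truth, cfg)
    controls, control_truth = make_control_probes(sim, cfg)
    probes = lib + controls
    truth = pd.DataFrame(
        lib_truth.to_dict("records") + control_truth.to_dict("records"),
        columns=_TRUTH_COLS,
    )

    acgh_tbl = simulate_acgh(probes, truth, cfg)
    age_tbl = simulate_age(probes, truth, sim, cfg)
    return SimBundle(
        cfg=cfg,
        sim=sim,
        reads=reads,
        read_truth=read_truth,
        probes=probes,
        truth=truth,
        acgh=acgh_tbl,
        age=age_tbl,
        discard_log=log,
    )
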