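"""Seeded synthetic-data generators with planted ground truth.

Every input the screen consumes can be generated here: a dependency matrix
with genes coupled to a driver gene and/or shifted in p53-mutant lines,
perturbation-study panels with replicate-level noise, patient cohorts with
driver-correlated expression, p53-status shifts, paired normals, stages,
subtypes and survival whose gene effect flips sign with p53 status, and
UTR/promoter sequences with planted seed sites and E-box motifs.

Defaults are the study conditions the screen is validated under (effect
sizes, sample sizes, noise levels); the planted gene sets and effect sizes
are echoed into a :class:`SyntheticTruth` so every downstream check is
self-describing.  The same seed always produces byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cohorts import CohortDataset
from .dependency import DependencyMatrix
from .motifs import EBOX_MOTIFS, SeedSite, _norm_dna, _revcomp
from .perturbation import PerturbationStudy

__all__ = [
    "SyntheticTruth",
    "MIR205_5P",
    "gen_dependency",
    "gen_perturbation_panel",
    "gen_cohorts",
    "gen_survival_cohort",
    "gen_sequences",
    "gen_screen_bundle",
]

#: mature miR-205-5p, the p53-inducible miRNA whose seed the screen scans for
MIR205_5P = "UCCUUCAUUCCACCGGAGUCUG"

DRIVER = "MYC"


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generator call.

    ``roles`` maps role names (myc_codependent, p53mut_dependent,
    myc_induced, p53_repressed, myc_correlated, mut_elevated,
    survival_interaction, ...) to the gene ids carrying them; ``effects``
    records the per-role effect sizes and ``params`` echoes every generator
    parameter.
    """

    seed: int
    params: dict = field(default_factory=dict)
    roles: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


def _pick_disjoint(rng, pool: list[str], sizes: list[int]) -> list[list[str]]:
    chosen = rng.choice(len(pool), size=sum(sizes), replace=False)
    out, k = [], 0
    for s in sizes:
        out.append([pool[i] for i in chosen[k:k + s]])
        k += s
    return out


# ---------------------------------------------------------------------------
# dependency matrix
# ---------------------------------------------------------------------------

def gen_dependency(n_genes: int = 200, n_lines: int = 40,
                   frac_mut: float = 0.5, n_codep: int = 10,
                   n_mutdep: int = 10, beta: float = 0.8,
                   delta: float = 0.6, noise_sd: float = 0.3,
                   driver_mut_shift: float = 0.6,
                   dual_genes: tuple[str, ...] = (),
                   seed: int = 0):
    """Dependency matrix with planted driver-coupled and p53-mut-dependent
    genes.

    The driver's own dependency is deeper by ``driver_mut_shift`` in mutant
    lines; this single parameter is what couples the two screen axes (genes
    tracking the driver inherit part of the mutant shift), mirroring the
    global positive correlation between co-dependency and mutant-specific
    dependency that the integrated screen reports.  ``dual_genes`` (ids
    from the gene universe) receive both planted roles.
    """
    if not (0.0 < frac_mut < 1.0):
        raise ValueError("frac_mut must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    genes = gene_ids(n_genes)
    lines = [f"L{i:03d}" for i in range(n_lines)]
    n_mut = int(round(frac_mut * n_lines))
    status = np.array(["mut"] * n_mut + ["wt"] * (n_lines - n_mut))
    rng.shuffle(status)
    mut = status == "mut"

    pool = [g for g in genes if g not in dual_genes]
    codep, mutdep = _pick_disjoint(rng, pool, [n_codep, n_mutdep])
    codep = sorted(set(codep) | set(dual_genes))
    mutdep = sorted(set(mutdep) | set(dual_genes))

    driver_dep = rng.normal(-1.0, 1.0, n_lines) - driver_mut_shift * mut
    baseline = rng.normal(0.0, 0.3, n_genes)
    noise = rng.normal(0.0, noise_sd, (n_genes, n_lines))
    scores = baseline[:, None] + noise
    idx = {g: i for i, g in enumerate(genes)}
    for g in codep:
        scores[idx[g]] += beta * driver_dep
    for g in mutdep:
        scores[idx[g]] += -delta * mut

    mat = pd.DataFrame(scores, index=genes, columns=lines)
    mat.loc[DRIVER] = driver_dep
    dep = DependencyMatrix(mat, pd.Series(status, index=lines,
                                          name="p53_status"))
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_genes=n_genes, n_lines=n_lines, frac_mut=frac_mut,
                    beta=beta, delta=delta, noise_sd=noise_sd,
                    driver_mut_shift=driver_mut_shift, driver=DRIVER),
        roles=dict(myc_codependent=codep, p53mut_dependent=mutdep,
                   dual=sorted(dual_genes)),
        effects=dict(myc_codependent={g: beta for g in codep},
                     p53mut_dependent={g: delta for g in mutdep}),
    )
    return dep, truth


# ---------------------------------------------------------------------------
# perturbation panels
# ---------------------------------------------------------------------------

def _pooled_t_p(diff, va, vb, na, nb):
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    from scipy import stats as _dist
    t = diff / se
    return 2.0 * _dist.t.sf(np.abs(t), na + nb - 2)


def gen_perturbation_panel(n_studies: int = 20, regulator: str = "MYC",
                           gain_frac: float = 0.5, n_genes: int = 200,
                           induced: tuple[str, ...] = (),
                           repressed: tuple[str, ...] = (),
                           effect: float = 1.0, n_reps: int = 4,
                           rep_sd: float = 0.3, seed: int = 0):
    """Panel of perturbation studies with replicate-level noise.

    ``induced``/``repressed`` genes carry a true log2 effect of
    ``+effect``/``-effect`` (in the regulator-gain direction); loss studies
    flip the sign at the data level so the biological direction is
    consistent.  Per-study p-values come from a pooled two-sample t over
    ``n_reps`` simulated replicates per arm (log2 scale, residual sd
    ``rep_sd``).  p53 panels contain activation (gain) studies only.
    """
    rng = np.random.default_rng(seed)
    genes = gene_ids(n_genes)
    if DRIVER not in genes:
        genes = genes + [DRIVER]
    eff = np.zeros(len(genes))
    gidx = {g: i for i, g in enumerate(genes)}
    for g in induced:
        eff[gidx[g]] = effect
    for g in repressed:
        eff[gidx[g]] = -effect
    if regulator == "p53":
        directions = ["gain"] * n_studies
    else:
        n_gain = int(round(gain_frac * n_studies))
        directions = ["gain"] * n_gain + ["loss"] * (n_studies - n_gain)
        rng.shuffle(directions)
    panel = []
    for s, direction in enumerate(directions):
        signed = eff if direction == "gain" else -eff
        ctrl = rng.normal(0.0, rep_sd, (len(genes), n_reps))
        trt = rng.normal(signed[:, None], rep_sd, (len(genes), n_reps))
        log2fc = trt.mean(axis=1) - ctrl.mean(axis=1)
        p = _pooled_t_p(log2fc, trt.var(axis=1, ddof=1),
                        ctrl.var(axis=1, ddof=1), n_reps, n_reps)
        panel.append(PerturbationStudy(
            study_id=f"{regulator}_{direction}_{s:02d}",
            regulator=regulator, direction=direction,
            table=pd.DataFrame({"gene": genes, "log2fc": log2fc,
                                "p": np.minimum(p, 1.0)})))
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_studies=n_studies, regulator=regulator,
                    gain_frac=gain_frac, n_genes=n_genes, effect=effect,
                    n_reps=n_reps, rep_sd=rep_sd),
        roles={f"{regulator.lower()}_induced": sorted(induced),
               f"{regulator.lower()}_repressed": sorted(repressed)},
        effects=dict(induced={g: effect for g in induced},
                     repressed={g: -effect for g in repressed}),
    )
    return panel, truth


# ---------------------------------------------------------------------------
# patient cohorts
# ---------------------------------------------------------------------------

CMS_LABELS = ["CMS1", "CMS2", "CMS3", "CMS4"]
CRIS_LABELS = ["CRIS-A", "CRIS-B", "CRIS-C", "CRIS-D", "CRIS-E"]


def gen_cohorts(n_cohorts: int = 15, n_p53_cohorts: int = 6,
                n_tumors: int = 100, n_pairs: int = 25,
                frac_mut: float = 0.5, n_genes: int = 200,
                n_corr: int = 10, corr_rho: float = 0.5,
                n_mutel: int = 10, mut_shift: float = 1.0,
                dual_genes: tuple[str, ...] = (),
                tumor_shift: float = 0.8, stage_slope: float = 0.4,
                cms2_shift: float = 1.0, noise_sd: float = 1.0,
                beta_wt: float = -0.8, beta_mut: float = 0.8,
                base_hazard: float = 0.02, censor_max: float = 120.0,
                seed: int = 0):
    """Patient cohorts with planted expression and survival structure.

    Expression is generated directly on the log2 scale: baseline per gene
    and cohort, plus a driver-correlation term (rho ``corr_rho`` for
    planted genes), a p53-mutant shift (``mut_shift`` sd, reported to the
    caller only in the first ``n_p53_cohorts`` cohorts), and — for
    ``dual_genes`` — a tumor-vs-normal shift, a stage trend, and a CMS2 /
    CRIS-C elevation.  Relapse-free survival is exponential with log-hazard
    ``beta_status * centered expression`` of the first dual gene, with
    independent uniform censoring on (1, ``censor_max``) months; the sign
    flip between wt and mutant strata is the planted interaction.
    """
    rng = np.random.default_rng(seed)
    genes = gene_ids(n_genes)
    pool = [g for g in genes if g not in dual_genes]
    corr_set, mutel_set = _pick_disjoint(rng, pool, [n_corr, n_mutel])
    corr_set = sorted(set(corr_set) | set(dual_genes))
    mutel_set = sorted(set(mutel_set) | set(dual_genes))
    surv_gene = sorted(dual_genes)[0] if dual_genes else None
    all_genes = genes + [DRIVER]
    gidx = {g: i for i, g in enumerate(all_genes)}

    cohorts = []
    for c in range(n_cohorts):
        cid = f"C{c:02d}"
        tumors = [f"{cid}_T{j:03d}" for j in range(n_tumors)]
        normals = [f"{cid}_N{j:03d}" for j in range(n_pairs)]
        n_mut = int(round(frac_mut * n_tumors))
        latent = np.array(["mut"] * n_mut + ["wt"] * (n_tumors - n_mut))
        rng.shuffle(latent)
        reported = latent if c < n_p53_cohorts \
            else np.array(["unknown"] * n_tumors)
        stage = rng.integers(1, 5, n_tumors)
        cms = rng.choice(CMS_LABELS, n_tumors)
        cris = rng.choice(CRIS_LABELS, n_tumors)
        driver_z = rng.normal(0.0, 1.0, n_tumors)
        mut = latent == "mut"

        baseline = rng.normal(8.0, 0.5, len(all_genes))
        expr = np.empty((len(all_genes), n_tumors + n_pairs))
        noise_t = rng.normal(0.0, noise_sd, (len(all_genes), n_tumors))
        noise_n = rng.normal(0.0, noise_sd, (len(all_genes), n_pairs))
        # gene-specific shared pair effect: makes tumor/normal pairing
        # informative without inducing cross-gene correlation
        pair_fx = rng.normal(0.0, 0.5, (len(all_genes), n_pairs))

        expr_t = baseline[:, None] + noise_t
        expr_n = baseline[:, None] + noise_n
        expr_t[gidx[DRIVER]] = baseline[gidx[DRIVER]] + noise_sd * driver_z
        for g in corr_set:
            i = gidx[g]
            expr_t[i] = (baseline[i]
                         + noise_sd * (corr_rho * driver_z
                                       + math.sqrt(1 - corr_rho**2)
                                       * noise_t[i] / noise_sd))
        for g in mutel_set:
            expr_t[gidx[g]] += mut_shift * noise_sd * mut
        for g in dual_genes:
            i = gidx[g]
            expr_t[i] += tumor_shift
            expr_t[i] += stage_slope * (stage - 2.5)
            expr_t[i] += cms2_shift * (cms == "CMS2")
            expr_t[i] += cms2_shift * np.isin(cris, ["CRIS-C", "CRIS-D"])
        # paired structure: shared pair effect on both members of a pair
        expr_t[:, :n_pairs] += pair_fx
        expr_n += pair_fx
        expr[:, :n_tumors] = expr_t
        expr[:, n_tumors:] = expr_n

        # survival driven by the dual gene's centered expression
        if surv_gene is not None:
            x = expr_t[gidx[surv_gene]]
            xc = x - x.mean()
            beta = np.where(mut, beta_mut, beta_wt)
            rate = base_hazard * np.exp(beta * xc)
        else:
            rate = np.full(n_tumors, base_hazard)
        T = rng.exponential(1.0 / rate)
        Cens = rng.uniform(1.0, censor_max, n_tumors)
        time = np.minimum(T, Cens)
        event = (T <= Cens).astype(int)

        ann = pd.DataFrame(index=pd.Index(tumors + normals, name="sample_id"))
        ann["tissue"] = ["tumor"] * n_tumors + ["normal"] * n_pairs
        pair_ids = [f"{cid}_P{j:03d}" for j in range(n_pairs)]
        ann["pair_id"] = (pair_ids + [""] * (n_tumors - n_pairs) + pair_ids)
        ann["p53_status"] = list(reported) + ["unknown"] * n_pairs
        ann["stage"] = list(stage) + [0] * n_pairs
        ann["time"] = list(np.round(time, 4)) + [np.nan] * n_pairs
        ann["event"] = list(event) + [0] * n_pairs
        ann["subtype_cms"] = list(cms) + ["none"] * n_pairs
        ann["subtype_cris"] = list(cris) + ["none"] * n_pairs
        cohorts.append(CohortDataset(
            cid, pd.DataFrame(expr, index=all_genes, columns=tumors + normals),
            ann))

    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_cohorts=n_cohorts, n_p53_cohorts=n_p53_cohorts,
                    n_tumors=n_tumors, n_pairs=n_pairs, frac_mut=frac_mut,
                    n_genes=n_genes, corr_rho=corr_rho, mut_shift=mut_shift,
                    tumor_shift=tumor_shift, stage_slope=stage_slope,
                    cms2_shift=cms2_shift, beta_wt=beta_wt,
                    beta_mut=beta_mut, base_hazard=base_hazard,
                    censor_max=censor_max, driver=DRIVER),
        roles=dict(myc_correlated=corr_set, mut_elevated=mutel_set,
                   survival_interaction=[surv_gene] if surv_gene else [],
                   dual=sorted(dual_genes)),
        effects=dict(myc_correlated={g: corr_rho for g in corr_set},
                     mut_elevated={g: mut_shift for g in mutel_set}),
    )
    return cohorts, truth


def gen_survival_cohort(n_per_stratum: int = 300, beta_wt: float = -0.8,
                        beta_mut: float = 0.8, base_hazard: float = 0.02,
                        censor_max: float = 120.0, seed: int = 0):
    """Standalone survival table with the p53-status sign-flip interaction.

    Expression ~ N(0,1); hazard = ``base_hazard * exp(beta_status * x)``;
    censoring uniform on (1, ``censor_max``) months.  Returns a DataFrame
    with columns sample_id, time, event, expression, stratum.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for stratum, beta in (("wt", beta_wt), ("mut", beta_mut)):
        x = rng.normal(0.0, 1.0, n_per_stratum)
        T = rng.exponential(1.0 / (base_hazard * np.exp(beta * x)))
        Cens = rng.uniform(1.0, censor_max, n_per_stratum)
        rows.append(pd.DataFrame({
            "sample_id": [f"{stratum}_{i:03d}" for i in range(n_per_stratum)],
            "time": np.round(np.minimum(T, Cens), 4),
            "event": (T <= Cens).astype(int),
            "expression": np.round(x, 6),
            "stratum": stratum,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

_SWAP = str.maketrans("ACGT", "CATG")


def _random_seq(rng, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _scrub(seq: str, patterns: list[str]) -> str:
    """Remove every exact occurrence of the given patterns by flipping the
    middle base of each hit (deterministic, no randomness needed)."""
    s = list(seq)
    for _ in range(10 * len(seq)):
        joined = "".join(s)
        hit = None
        for pat in patterns:
            i = joined.find(pat)
            if i >= 0:
                hit = (i, pat)
                break
        if hit is None:
            return joined
        i, pat = hit
        j = i + len(pat) // 2
        s[j] = s[j].translate(_SWAP)
    raise RuntimeError("background scrub did not converge")


def _site_insert(site_type: str, seed6: str, m8c: str, rng) -> str:
    """10-nt sequence to splice in for a planted site (seed core at offset
    2).  Flanks are chosen so the planted type is exactly what a scan will
    report."""
    not_m8 = str(rng.choice([b for b in "ACGT" if b != m8c]))
    not_a = str(rng.choice(list("CGT")))
    if site_type == "8mer":
        return not_a + m8c + seed6 + "A" + not_m8
    if site_type == "7mer-m8":
        return not_a + m8c + seed6 + not_a + not_m8
    if site_type == "7mer-A1":
        return not_a + not_m8 + seed6 + "A" + not_a
    return not_a + not_m8 + seed6 + not_a + not_m8  # 6mer


def _scrub_protected(seq: str, patterns: list[str], protected: set[int],
                     allowed_starts: set[int]) -> str:
    """Remove accidental pattern occurrences (e.g. created at the junction
    of a planted insert and the background) by flipping a base outside the
    ``protected`` positions; occurrences starting at ``allowed_starts``
    (the planted ones) are kept."""
    s = list(seq)
    for _ in range(10 * len(seq)):
        joined = "".join(s)
        hit = None
        for pat in patterns:
            i = joined.find(pat)
            while i >= 0:
                if i not in allowed_starts:
                    hit = (i, pat)
                    break
                i = joined.find(pat, i + 1)
            if hit:
                break
        if hit is None:
            return joined
        i, pat = hit
        for j in range(i, i + len(pat)):
            if j not in protected:
                s[j] = s[j].translate(_SWAP)
                break
        else:
            raise RuntimeError("accidental site fully inside a planted "
                               "region; cannot scrub")
    raise RuntimeError("protected scrub did not converge")


def gen_sequences(n_utrs: int = 10, utr_length: int = 1000,
                  mirna: str = MIR205_5P, sites_per_utr: int = 2,
                  n_orthologs: int = 5, conservation_p: float = 0.8,
                  n_promoters: int = 5, promoter_length: int = 2000,
                  motifs_per_promoter: int = 2, gc: float = 0.4,
                  seed: int = 0):
    """UTRs with planted seed sites (plus orthologs), and promoters with
    planted E-box motifs.

    Backgrounds are i.i.d. with the given GC content and are scrubbed of
    accidental seed cores / motifs so that the planted coordinates are the
    exhaustive truth.  Each ortholog copies each planted site with
    probability ``conservation_p`` and scrambles its core otherwise;
    orthologs share the reference background (offset 0 mapping).

    Returns ``(utrs, orthologs, promoters, truth)`` where ``utrs`` and
    ``promoters`` map id -> sequence and ``orthologs`` maps utr id ->
    {species: sequence}.
    """
    rng = np.random.default_rng(seed)
    mir = _norm_dna(mirna, "mirna")
    seed6 = _revcomp(mir[1:7])
    m8c = mir[7].translate(str.maketrans("ACGT", "TGCA"))
    site_cycle = ["8mer", "7mer-m8", "7mer-A1", "6mer"]
    species = [f"sp{i+1}" for i in range(n_orthologs)]

    utrs: dict[str, str] = {}
    orthologs: dict[str, dict[str, str]] = {}
    truth_sites: dict[str, list[dict]] = {}
    for u in range(n_utrs):
        uid = f"UTR{u:03d}"
        bg = _scrub(_random_seq(rng, utr_length, gc), [seed6])
        slots = np.sort(rng.choice(
            np.arange(1, (utr_length - 20) // 12) * 12,
            size=sites_per_utr, replace=False))
        chars = list(bg)
        placed = []
        for s_i, pos in enumerate(slots):
            stype = site_cycle[(u + s_i) % 4]
            ins = _site_insert(stype, seed6, m8c, rng)
            chars[pos:pos + len(ins)] = list(ins)
            placed.append((stype, int(pos)))
        # truth coordinates from the construction layout (core at pos + 2)
        site_truth = []
        for stype, pos in placed:
            core_start = pos + 2
            start = core_start - 1 if stype in ("8mer", "7mer-m8") \
                else core_start
            end = start + {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7,
                           "6mer": 6}[stype]
            site_truth.append(dict(site_type=stype, start=int(start),
                                   end=int(end), core_start=int(core_start)))
        protected = {j for t in site_truth
                     for j in range(t["core_start"] - 1,
                                    t["core_start"] + 7)}
        seq = _scrub_protected("".join(chars), [seed6], protected,
                               {t["core_start"] for t in site_truth})
        utrs[uid] = seq
        # orthologs: copy or scramble each site core
        orth = {}
        conserved_in: dict[int, list[str]] = {t["core_start"]: []
                                              for t in site_truth}
        for sp in species:
            ochars = list(seq)
            for t in site_truth:
                if rng.random() >= conservation_p:
                    cs = t["core_start"]
                    core = seq[cs:cs + 6]
                    ochars[cs:cs + 6] = list(
                        core.translate(str.maketrans("ACGT", "TGCA")))
                else:
                    conserved_in[t["core_start"]].append(sp)
            orth[sp] = "".join(ochars)
        for t in site_truth:
            t["conserved_in"] = conserved_in[t["core_start"]]
        orthologs[uid] = orth
        truth_sites[uid] = site_truth

    promoters: dict[str, str] = {}
    truth_motifs: dict[str, list[dict]] = {}
    motif_seqs = list(EBOX_MOTIFS)
    scrub_pats = sorted({m for mm in motif_seqs
                         for m in (mm, _revcomp(mm))})
    for p in range(n_promoters):
        pid = f"PROM{p:03d}"
        bg = _scrub(_random_seq(rng, promoter_length, gc), scrub_pats)
        slots = np.sort(rng.choice(
            np.arange(1, (promoter_length - 12) // 10) * 10,
            size=motifs_per_promoter, replace=False))
        chars = list(bg)
        mt = []
        for s_i, pos in enumerate(slots):
            motif = motif_seqs[(p + s_i) % len(motif_seqs)]
            chars[pos:pos + len(motif)] = list(motif)
            mt.append(dict(motif_id=EBOX_MOTIFS[motif], start=int(pos),
                           end=int(pos + len(motif)), motif=motif))
        protected = {j for t in mt for j in range(t["start"], t["end"])}
        promoters[pid] = _scrub_protected(
            "".join(chars), scrub_pats, protected,
            {t["start"] for t in mt})
        truth_motifs[pid] = mt

    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_utrs=n_utrs, utr_length=utr_length, mirna=mirna,
                    sites_per_utr=sites_per_utr, n_orthologs=n_orthologs,
                    conservation_p=conservation_p, n_promoters=n_promoters,
                    promoter_length=promoter_length,
                    motifs_per_promoter=motifs_per_promoter, gc=gc),
        extras=dict(sites=truth_sites, motifs=truth_motifs,
                    species=species),
    )
    return utrs, orthologs, promoters, truth


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def gen_screen_bundle(n_genes: int = 2000, n_lines: int = 40,
                      n_studies: int = 20, n_cohorts: int = 15,
                      n_p53_cohorts: int = 6, n_tumors: int = 100,
                      seed: int = 0, planted_gene: str | None = None,
                      null: bool = False):
    """Generate every input of the end-to-end screen with one gene planted
    in all roles (the screen's exemplar-hit construction).

    With ``null=True`` all effects are zero (calibration conditions).
    Returns a dict with keys ``dependency``, ``myc_panel``, ``p53_panel``,
    ``cohorts`` and a merged :class:`SyntheticTruth`.
    """
    rng = np.random.default_rng(seed)
    sub = [int(x) for x in rng.integers(0, 2**31 - 1, 4)]
    if planted_gene is None:
        planted_gene = f"G{int(rng.integers(0, n_genes)):04d}"
    dual = () if null else (planted_gene,)
    n_planted = 0 if null else 10

    dep, dep_truth = gen_dependency(
        n_genes=n_genes, n_lines=n_lines, seed=sub[0],
        n_codep=n_planted, n_mutdep=n_planted,
        beta=0.0 if null else 0.8, delta=0.0 if null else 0.6,
        driver_mut_shift=0.0 if null else 0.6, dual_genes=dual)
    myc_panel, myc_truth = gen_perturbation_panel(
        n_studies=n_studies, regulator="MYC", n_genes=n_genes, seed=sub[1],
        induced=dual, effect=0.0 if null else 1.0)
    p53_panel, p53_truth = gen_perturbation_panel(
        n_studies=n_studies, regulator="p53", n_genes=n_genes, seed=sub[2],
        repressed=dual, effect=0.0 if null else 1.0)
    cohorts, cohort_truth = gen_cohorts(
        n_cohorts=n_cohorts, n_p53_cohorts=n_p53_cohorts, n_tumors=n_tumors,
        n_genes=n_genes, seed=sub[3], dual_genes=dual,
        n_corr=n_planted, n_mutel=n_planted,
        corr_rho=0.0 if null else 0.5, mut_shift=0.0 if null else 1.0,
        tumor_shift=0.0 if null else 0.8,
        stage_slope=0.0 if null else 0.4, cms2_shift=0.0 if null else 1.0,
        beta_wt=0.0 if null else -0.8, beta_mut=0.0 if null else 0.8)

    roles: dict = {"planted": [planted_gene] if not null else []}
    for t in (dep_truth, cohort_truth, myc_truth, p53_truth):
        for name, ids in t.roles.items():
            roles.setdefault(name, sorted(set(roles.get(name, [])) | set(ids)))
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_genes=n_genes, n_lines=n_lines, n_studies=n_studies,
                    n_cohorts=n_cohorts, n_tumors=n_tumors, null=null,
                    subseeds=sub),
        roles=roles,
    )
    return dict(dependency=dep, myc_panel=myc_panel, p53_panel=p53_panel,
                cohorts=cohorts, truth=truth, planted_gene=planted_gene)
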