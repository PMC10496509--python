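"""miRNA seed matching and E-box motif scanning.

Seed sites follow the canonical site hierarchy: with the miRNA written
5'->3', the 6mer site is the reverse complement of miRNA positions 2-7 in
the target; adding a match to position 8 on the 5' side gives the 7mer-m8,
an adenosine opposite position 1 on the 3' side gives the 7mer-A1, and both
together the 8mer.  Overlapping definitions at one seed-match locus are
reported at their most specific type only (8mer > 7mer-m8 > 7mer-A1 >
6mer).  All coordinates are 0-based half-open on the given sequence;
matching is strand-specific (a site lives on the mRNA strand only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

__all__ = ["SeedSite", "MotifHit", "find_seed_sites", "conservation_flag",
           "mutate_sms", "scan_ebox", "EBOX_MOTIFS"]

_COMP = str.maketrans("ACGTN", "TGCAN")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_RANK = {t: i for i, t in enumerate(SITE_TYPES)}  # 0 = most specific

EBOX_MOTIFS = {"CACGTG": "MYC", "CAGCTG": "AP4"}


def _norm_dna(seq: str, name: str) -> str:
    s = seq.upper().replace("U", "T")
    if set(s) - set("ACGTN"):
        raise ValueError(f"{name}: unexpected characters "
                         f"{sorted(set(s) - set('ACGTN'))}")
    return s


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SeedSite:
    """A located miRNA seed-match site.

    ``conserved`` is tri-state: True / False / None (unknown, e.g. the site
    could not be mapped into the orthologs).  ``core_start`` is the start
    of the 6-nt seed core (the bases pairing miRNA positions 2-7), which is
    the locus identity used when comparing sites across species.
    """

    site_type: str
    start: int
    end: int
    matched_seq: str
    conserved: bool | None = None

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start != len(self.matched_seq):
            raise ValueError("matched_seq length inconsistent with span")

    @property
    def core_start(self) -> int:
        return self.start + 1 if self.site_type in ("8mer", "7mer-m8") \
            else self.start


@dataclass(frozen=True)
class MotifHit:
    """An exact transcription-factor motif occurrence."""

    motif_id: str
    start: int
    end: int
    strand: str
    sequence: str  # plus-strand slice of the scanned sequence


def find_seed_sites(mirna: str, utr: str,
                    site_types=SITE_TYPES) -> list[SeedSite]:
    """Locate seed-match sites for ``mirna`` (RNA or DNA, 5'->3') in
    ``utr``.

    Each seed-match locus is classified at its most specific admissible
    type; ``site_types`` then filters which classes are returned.  Windows
    containing ambiguous bases (N) are skipped with a warning.
    """
    mir = _norm_dna(mirna, "mirna")
    if len(mir) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    seq = _norm_dna(utr, "utr")
    bad = set(site_types) - set(SITE_TYPES)
    if bad:
        raise ValueError(f"unknown site types {sorted(bad)}")
    seed6 = _revcomp(mir[1:7])
    m8_base = mir[7].translate(_COMP)  # complement of miRNA position 8
    if "N" in seq:
        warnings.warn("ambiguous bases (N) present; overlapping windows "
                      "skipped", stacklevel=2)
    sites: list[SeedSite] = []
    for i in range(len(seq) - 5):
        core = seq[i:i + 6]
        if "N" in core:
            continue
        if core != seed6:
            continue
        has_m8 = i >= 1 and seq[i - 1] == m8_base
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            t, s, e = "8mer", i - 1, i + 7
        elif has_m8:
            t, s, e = "7mer-m8", i - 1, i + 6
        elif has_a1:
            t, s, e = "7mer-A1", i, i + 7
        else:
            t, s, e = "6mer", i, i + 6
        if t in site_types:
            sites.append(SeedSite(t, s, e, utr[s:e]))
    return sites


def _alignment_maps(aligned: str):
    """Ungapped-position -> alignment-column and inverse for one aligned
    sequence (gaps '-')."""
    pos2col = [i for i, ch in enumerate(aligned) if ch != "-"]
    col2pos = {c: p for p, c in enumerate(pos2col)}
    return pos2col, col2pos


def conservation_flag(sites: list[SeedSite], mirna: str,
                      orthologs: dict[str, str], k: int | None = None,
                      offsets: dict[str, int] | None = None,
                      alignment: dict[str, str] | None = None,
                      reference: str | None = None) -> list[SeedSite]:
    """Flag each site as conserved when a site of the same or a more
    specific type sits at the homologous seed-core position in at least
    ``k`` orthologs (default: a majority of those provided).

    Homologous coordinates come either from ``offsets`` (per-species
    integer shift added to the reference coordinate; missing species
    default to 0) or from ``alignment`` — a gapped multiple alignment given
    as ``{name: aligned_seq}`` that must include the reference sequence
    under ``reference``.  A site whose core cannot be mapped into any
    ortholog is flagged ``None`` (unknown).
    """
    if len(orthologs) < 2:
        raise ValueError("need at least 2 ortholog sequences")
    if k is None:
        k = len(orthologs) // 2 + 1
    ortho_sites = {name: find_seed_sites(mirna, seq)
                   for name, seq in orthologs.items()}
    by_core = {name: {s.core_start: s for s in ss}
               for name, ss in ortho_sites.items()}

    ref_pos2col = None
    ortho_col2pos: dict[str, dict[int, int]] = {}
    if alignment is not None:
        if reference is None or reference not in alignment:
            raise ValueError("alignment mode needs the reference row name")
        ref_pos2col, _ = _alignment_maps(alignment[reference])
        for name in orthologs:
            if name not in alignment:
                raise ValueError(f"ortholog {name!r} missing from alignment")
            _, col2pos = _alignment_maps(alignment[name])
            ortho_col2pos[name] = col2pos

    out: list[SeedSite] = []
    for site in sites:
        n_conserved = 0
        n_mappable = 0
        for name, seq in orthologs.items():
            if alignment is not None:
                if site.core_start >= len(ref_pos2col):
                    continue
                col = ref_pos2col[site.core_start]
                pos = ortho_col2pos[name].get(col)
                if pos is None:
                    continue
            else:
                pos = site.core_start + (offsets or {}).get(name, 0)
            if not (0 <= pos <= len(seq) - 6):
                continue
            n_mappable += 1
            hit = by_core[name].get(pos)
            if hit is not None and _RANK[hit.site_type] <= _RANK[site.site_type]:
                n_conserved += 1
        if n_conserved >= k:
            flag: bool | None = True
        elif n_mappable == len(orthologs):
            flag = False
        elif n_mappable == 0:
            flag = None
        else:
            # partially mappable: decidable only if the answer cannot flip
            flag = False if n_conserved + (len(orthologs) - n_mappable) < k \
                else None
        out.append(replace(site, conserved=flag))
    return out


def mutate_sms(utr: str, site: SeedSite, strategy: str = "complement") -> str:
    """Disrupt the seed-matching sequence of ``site`` inside ``utr``.

    The default strategy complements each base of the 6-nt seed core
    (leaving length and all other positions untouched); the result is
    verified to contain no seed site of any type overlapping the original
    locus, falling back to deterministic alternative substitutions in the
    (rare) case a substitution recreates a site.
    """
    if strategy != "complement":
        raise ValueError(f"unknown strategy {strategy!r}")
    if not (0 <= site.start < site.end <= len(utr)):
        raise ValueError("site out of bounds")
    seq = _norm_dna(utr, "utr")
    core_s = site.core_start
    core = seq[core_s:core_s + 6]
    # original site sequence defines the miRNA seed it matched
    seed6 = core
    mir_2_7 = _revcomp(seed6)
    # reconstruct an 8-mer miRNA sufficient for rescanning this locus
    m8 = seq[core_s - 1].translate(_COMP) if core_s >= 1 else "A"
    pseudo_mirna = "A" + mir_2_7 + m8

    candidates = [
        core.translate(_COMP),          # elementwise complement
        core[::-1],                     # reverse
        core.translate(_COMP)[::-1],    # reverse complement
        core[3:] + core[:3],            # rotation
    ]
    for new_core in candidates:
        if new_core == core:
            continue
        mutated = seq[:core_s] + new_core + seq[core_s + 6:]
        rescan = find_seed_sites(pseudo_mirna, mutated)
        if not any(s.start < site.end and s.end > site.start for s in rescan):
            return mutated
    raise RuntimeError("could not disrupt the seed site deterministically")


def scan_ebox(promoter: str, motifs: dict[str, str] | None = None
              ) -> list[MotifHit]:
    """Exact-match scan of E-box-family motifs on both strands.

    ``motifs`` maps motif sequence -> id (default: the canonical c-MYC
    E-box CACGTG and the AP4-associated variant CAGCTG).  Palindromic
    motifs are reported once per position (strand '+'); coordinates are
    0-based half-open on the input.
    """
    seq = _norm_dna(promoter, "promoter")
    if motifs is None:
        motifs = EBOX_MOTIFS
    hits: list[MotifHit] = []
    for motif, motif_id in motifs.items():
        m = _norm_dna(motif, "motif")
        rc = _revcomp(m)
        L = len(m)
        for i in range(len(seq) - L + 1):
            window = seq[i:i + L]
            if window == m:
                hits.append(MotifHit(motif_id, i, i + L, "+",
                                     promoter[i:i + L]))
            if window == rc and rc != m:
                hits.append(MotifHit(motif_id, i, i + L, "-",
                                     promoter[i:i + L]))
    hits.sort(key=lambda h: (h.start, h.motif_id, h.strand))
    return hits
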