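"""Forward simulator of return-to-growth (RTG) recombination in polyploid yeast.

The simulator emulates an intraspecies hybrid *Saccharomyces cerevisiae*
genome of configurable ploidy (triploid / tetraploid, with optional
aneuploid chromosomes) carrying dense heterozygous markers, and the outcome
of an aborted meiosis: after premeiotic replication each of the ``p``
homologs is duplicated into two sister chromatids, Spo11-type double-strand
breaks are placed along the chromosomes, each break resolves as a crossover
(CO, reciprocal exchange between two non-sister chromatids downstream of the
breakpoint plus a short conversion tract) or a non-crossover (NCO, one-sided
gene-conversion tract), and the 2p chromatids segregate one-sister-per-
homolog into the mother and the daughter cell of the first mitotic division.
Optionally one chromosome missegregates 2:0, producing a complementary
whole-chromosome gain and loss in the pair.

Everything is recorded in an :class:`RTGSimTruth` object so downstream
callers can be scored against known truth, and the observable surface
(per-marker allele depths as VCF 4.2, windowed depth tracks as TSV) matches
the formats the real pipeline consumes.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenomeSpec",
    "ParentGenome",
    "CellState",
    "RecombinationEvent",
    "ForcedCrossover",
    "RTGSimTruth",
    "NoiseModel",
    "simulate_parent",
    "simulate_rtg",
    "parent_cell",
    "emit_observations",
    "emit_depth_track",
    "write_vcf",
    "write_truth_bed",
]

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
]

_BASES = np.array(["A", "C", "G", "T"])


def default_chrom_names(n: int) -> tuple[str, ...]:
    """Yeast-style chromosome names: chrI..chrXVI, then chr17, chr18, ..."""
    names = [f"chr{_ROMAN[i]}" if i < len(_ROMAN) else f"chr{i + 1}" for i in range(n)]
    return tuple(names)


@dataclass(frozen=True)
class GenomeSpec:
    """Static description of the simulated hybrid genome.

    Parameters
    ----------
    chrom_lengths:
        Chromosome lengths in bp.
    ploidy:
        Per-chromosome homolog count; supports aneuploidy (e.g. 3n plus one
        extra chromosome III = ploidy 4 on that chromosome). Must be >= 2.
    marker_density:
        Heterozygous markers per kbp (the study's hybrids carry ~3.4/kbp,
        ~40 K markers over a ~12 Mb genome).
    loh_blocks:
        Pre-existing loss-of-heterozygosity blocks, ``(chrom_index, start,
        end)`` 0-based half-open in bp. All haplotypes agree inside a block,
        so no heterozygous marker is placed there.
    subtel_margin:
        Subtelomeric margin per chromosome end (bp), exported for downstream
        positional filtering; markers ARE placed there (real subtelomeres
        carry markers, they are just unreliable).
    haplotype_block_mean:
        Mean length (bp) of the parental ancestry blocks. An intraspecies
        hybrid is a mosaic of donor lineages, so the Alt dosage and the set
        of carrier haplotypes are locally constant; block lengths are
        exponential with this mean. ``None`` draws every marker
        independently (no haplotype structure — recombination then produces
        only heavily fragmented dosage-shift runs).
    seed:
        Seed for the parental-genome draw.
    """

    chrom_lengths: tuple[int, ...]
    ploidy: tuple[int, ...]
    marker_density: float = 3.4
    loh_blocks: tuple[tuple[int, int, int], ...] = ()
    subtel_margin: int = 25_000
    haplotype_block_mean: float | None = 50_000.0
    seed: int = 0
    chrom_names: tuple[str, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "chrom_lengths", tuple(int(x) for x in self.chrom_lengths))
        object.__setattr__(self, "ploidy", tuple(int(x) for x in self.ploidy))
        object.__setattr__(
            self, "loh_blocks", tuple((int(c), int(s), int(e)) for c, s, e in self.loh_blocks)
        )
        if len(self.ploidy) != len(self.chrom_lengths):
            raise ValueError("ploidy must list one value per chromosome")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if any(p < 2 for p in self.ploidy):
            raise ValueError("ploidy must be >= 2 on every chromosome")
        if not self.marker_density > 0:
            raise ValueError("marker density must be > 0")
        for c, s, e in self.loh_blocks:
            if not (0 <= c < len(self.chrom_lengths)):
                raise ValueError(f"LOH block references unknown chromosome index {c}")
            if not (0 <= s < e <= self.chrom_lengths[c]):
                raise ValueError(f"LOH block ({c}, {s}, {e}) outside chromosome bounds")
        if self.chrom_names is None:
            object.__setattr__(self, "chrom_names", default_chrom_names(len(self.chrom_lengths)))
        elif len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names must match chrom_lengths")
        else:
            object.__setattr__(self, "chrom_names", tuple(self.chrom_names))

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_lengths)

    @property
    def base_ploidy(self) -> int:
        """Modal ploidy across chromosomes — the genome's nominal n."""
        values, counts = np.unique(np.array(self.ploidy), return_counts=True)
        return int(values[np.argmax(counts)])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chrom_lengths"] = list(self.chrom_lengths)
        d["ploidy"] = list(self.ploidy)
        d["loh_blocks"] = [list(b) for b in self.loh_blocks]
        d["chrom_names"] = list(self.chrom_names)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeSpec":
        d = dict(d)
        if d.get("chrom_names") is not None:
            d["chrom_names"] = tuple(d["chrom_names"])
        d["loh_blocks"] = tuple(tuple(b) for b in d.get("loh_blocks", ()))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GenomeSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ParentGenome:
    """A simulated polyploid parent: marker positions and phased haplotypes.

    ``haplotypes[c]`` has shape ``(p_c, n_markers_c)`` with entries 0 (Ref)
    or 1 (Alt). Every placed marker is heterozygous (0 < dosage < p);
    positions inside pre-existing LOH blocks carry no marker at all.
    """

    spec: GenomeSpec
    positions: list[np.ndarray]        # per chromosome, 1-based bp, sorted
    haplotypes: list[np.ndarray]       # per chromosome, (ploidy, n_markers) of 0/1
    ref_alleles: list[np.ndarray]      # per chromosome, dtype <U1
    alt_alleles: list[np.ndarray]

    def dosage(self, c: int) -> np.ndarray:
        """Parental Alt dosage k at every marker of chromosome ``c``."""
        return self.haplotypes[c].sum(axis=0)

    @property
    def n_markers(self) -> int:
        return int(sum(len(p) for p in self.positions))

    def marker_frame(self) -> pd.DataFrame:
        """All markers as a catalogue-shaped DataFrame (chrom, pos, ref, alt, k, p)."""
        frames = []
        for c in range(self.spec.n_chroms):
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": self.spec.chrom_names[c],
                        "pos": self.positions[c],
                        "ref": self.ref_alleles[c],
                        "alt": self.alt_alleles[c],
                        "k": self.dosage(c),
                        "p": self.spec.ploidy[c],
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        df["af"] = df["k"] / df["p"]
        return df


@dataclass(frozen=True)
class RecombinationEvent:
    """One resolved double-strand break.

    ``homologs``/``sisters`` identify the two involved chromatids; for a CO
    the exchange is reciprocal downstream of ``tract_end`` and the recipient
    ``(homologs[0], sisters[0])`` is gene-converted over
    ``[pos, tract_end)``; for an NCO only the conversion tract applies.
    Marker-index bounds (half-open) are cached in ``i_tract``.
    """

    kind: str                      # "CO" | "NCO"
    chrom: int
    pos: int                       # breakpoint, 1-based bp
    tract_end: int                 # conversion tract end (exclusive), bp
    homologs: tuple[int, int]
    sisters: tuple[int, int]
    i_tract: tuple[int, int]
    forced: bool = False


@dataclass(frozen=True)
class ForcedCrossover:
    """Deterministically injected CO, used to build controlled test cases.

    ``split=True`` forces the two recombinant chromatids into different
    cells so the event is guaranteed to show as a reciprocal dosage shift.
    """

    chrom: int
    pos: int
    homologs: tuple[int, int] = (0, 1)
    sisters: tuple[int, int] = (0, 0)
    tract_len: int = 0
    split: bool = True


@dataclass
class CellState:
    """Chromatid content of one cell (mother, daughter, or the parent itself)."""

    parent: ParentGenome
    chromatids: list[list[np.ndarray]]   # per chromosome, list of 0/1 allele vectors
    name: str = "cell"

    def copy_number(self, c: int) -> int:
        return len(self.chromatids[c])

    def dosage(self, c: int) -> np.ndarray:
        if not self.chromatids[c]:
            return np.zeros(len(self.parent.positions[c]), dtype=int)
        return np.sum(self.chromatids[c], axis=0)


@dataclass
class RTGSimTruth:
    """Complete record of one simulated RTG mother-daughter outcome."""

    parent: ParentGenome
    events: list[RecombinationEvent]
    sister_to_mother: list[np.ndarray]       # per chromosome, per homolog: 0/1
    missegregation: tuple[int, int, bool] | None   # (chrom, homolog, to_mother)
    mother_dosage: list[np.ndarray]
    daughter_dosage: list[np.ndarray]

    def parent_dosage(self, c: int) -> np.ndarray:
        return self.parent.dosage(c)

    def cell_dosage(self, cell: str, c: int) -> np.ndarray:
        return (self.mother_dosage if cell == "mother" else self.daughter_dosage)[c]

    def shifted_mask(self, cell: str, c: int) -> np.ndarray:
        """Boolean mask of markers whose true dosage differs from the parent."""
        return self.cell_dosage(cell, c) != self.parent_dosage(c)

    def shift_tracts(self, cell: str, min_markers: int = 1) -> pd.DataFrame:
        """Maximal runs of dosage-shifted markers as a (chrom, start, end) table.

        Coordinates are 0-based half-open in bp ([first marker - 1, last
        marker)); ``i0``/``i1`` give the half-open marker-index range.
        """
        rows = []
        for c in range(self.parent.spec.n_chroms):
            mask = self.shifted_mask(cell, c)
            pos = self.parent.positions[c]
            for i0, i1 in _runs(mask):
                if i1 - i0 < min_markers:
                    continue
                delta = self.cell_dosage(cell, c)[i0:i1] - self.parent_dosage(c)[i0:i1]
                rows.append(
                    {
                        "chrom": self.parent.spec.chrom_names[c],
                        "start": int(pos[i0]) - 1,
                        "end": int(pos[i1 - 1]),
                        "i0": i0,
                        "i1": i1,
                        "n_markers": i1 - i0,
                        "direction": "gain_alt" if delta.mean() > 0 else "loss_alt",
                    }
                )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "i0", "i1", "n_markers", "direction"])

    def scaled_dosage(self, cell: str, c: int) -> np.ndarray:
        """Dosage expressed at the nominal ploidy: p * d / copy_number.

        This is what an AF-based caller infers. For a euploid cell it
        equals the raw dosage; on a missegregated chromosome the raw
        mother+daughter counts still sum to 2x the parent (both sisters
        exist, just in one cell), but the scaled dosages do not — the
        missegregation is only visible in AF space (and in read depth).
        """
        p = self.parent.spec.ploidy[c]
        d = self.cell_dosage(cell, c).astype(float)
        cn = p
        if self.missegregation is not None and self.missegregation[0] == c:
            cn = p + 1 if (cell == "mother") == self.missegregation[2] else p - 1
        return d * p / cn

    def conversion_mask(self, c: int) -> np.ndarray:
        """Markers of chromosome ``c`` inside any event's conversion tract.

        Gene conversion copies the donor's alleles over the recipient's, so
        total allele counts across the chromatid pool are conserved only
        outside these tracts (conversion is the non-Mendelian, 3:1-style
        part of recombination); CO exchange downstream of the tract is a
        swap and conserves counts everywhere.
        """
        mask = np.zeros(len(self.parent.positions[c]), dtype=bool)
        for ev in self.events:
            if ev.chrom == c:
                mask[ev.i_tract[0] : ev.i_tract[1]] = True
        return mask

    def chromatid_cell(self, chrom: int, homolog: int, sister: int) -> str:
        """Which cell received the given chromatid."""
        if self.missegregation is not None:
            mc, mh, to_mother = self.missegregation
            if mc == chrom and mh == homolog:
                return "mother" if to_mother else "daughter"
        s = self.sister_to_mother[chrom][homolog]
        return "mother" if sister == s else "daughter"

    def event_cells(self, ev: RecombinationEvent) -> tuple[str, str]:
        """Destination cells of the two chromatids involved in an event."""
        return (
            self.chromatid_cell(ev.chrom, ev.homologs[0], ev.sisters[0]),
            self.chromatid_cell(ev.chrom, ev.homologs[1], ev.sisters[1]),
        )


@dataclass(frozen=True)
class NoiseModel:
    """Sequencing-observation model for the simulator's emitted files.

    ``mean_depth`` reads per marker, drawn Poisson by default or
    negative-binomial with dispersion ``nb_dispersion`` (variance
    ``mu + mu^2/r``); per-read error rate flips a read's allele; ``dropout``
    removes a marker from the emitted VCF entirely.
    """

    mean_depth: float = 50.0
    depth_model: str = "poisson"     # "poisson" | "nb"
    nb_dispersion: float = 10.0
    error_rate: float = 0.002
    dropout: float = 0.0

    def __post_init__(self):
        if self.mean_depth < 0:
            raise ValueError("mean depth must be >= 0")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error rate must be in [0, 0.5)")
        if not (0 <= self.dropout <= 1):
            raise ValueError("dropout must be a probability")
        if self.depth_model not in ("poisson", "nb"):
            raise ValueError("depth_model must be 'poisson' or 'nb'")

    def draw_depth(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.depth_model == "poisson":
            return rng.poisson(self.mean_depth, size=n)
        r = self.nb_dispersion
        return rng.negative_binomial(r, r / (r + self.mean_depth), size=n)


def _runs(mask: np.ndarray):
    """Half-open index ranges of maximal True runs."""
    if mask.size == 0:
        return
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    yield from zip(starts.tolist(), ends.tolist())


def _sample_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """Draw ``n`` distinct 1-based positions on [1, length] without a full permutation."""
    if n > length:
        raise ValueError(f"requested {n} markers on a {length} bp chromosome")
    got = np.empty(0, dtype=np.int64)
    while len(got) < n:
        extra = rng.integers(1, length + 1, size=int((n - len(got)) * 1.2) + 16)
        got = np.unique(np.concatenate([got, extra]))
    # unique() sorts; subsample back to n while keeping order
    if len(got) > n:
        keep = np.sort(rng.choice(len(got), size=n, replace=False))
        got = got[keep]
    return got


def _draw_dosages(rng, p: int, size: int, dosage_weights) -> np.ndarray:
    if dosage_weights and p in dosage_weights:
        w = np.asarray(dosage_weights[p], dtype=float)
        if len(w) != p - 1:
            raise ValueError(f"dosage_weights[{p}] must have length {p - 1}")
        return rng.choice(np.arange(1, p), size=size, p=w / w.sum())
    return rng.integers(1, p, size=size)


def simulate_parent(spec: GenomeSpec, dosage_weights=None) -> ParentGenome:
    """Draw a heterozygous polyploid parent genome from a :class:`GenomeSpec`.

    Marker positions are uniform per chromosome at ``spec.marker_density``
    markers/kbp; markers falling inside pre-existing LOH blocks are removed.
    The parent is an ancestry mosaic: chromosomes are partitioned into
    exponential blocks of mean ``spec.haplotype_block_mean`` bp, and within
    a block every marker shares one Alt dosage k (drawn from {1..p-1},
    uniformly unless ``dosage_weights`` — a mapping ploidy -> weight vector
    of length p-1 — says otherwise) and one set of k carrier haplotypes.
    This block-constant phase is what lets a single recombination event
    shift many consecutive markers, as observed in real hybrid data; with
    ``haplotype_block_mean=None`` every marker draws dosage and carriers
    independently instead. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    positions, haplotypes, refs, alts = [], [], [], []
    for c, (length, p) in enumerate(zip(spec.chrom_lengths, spec.ploidy)):
        n = int(round(spec.marker_density * length / 1000.0))
        pos = _sample_positions(rng, length, n)
        # pre-existing LOH blocks carry no heterozygous marker
        for bc, bs, be in spec.loh_blocks:
            if bc == c:
                pos = pos[(pos <= bs) | (pos > be)]
        m = len(pos)
        hap = np.zeros((p, m), dtype=np.int8)
        if spec.haplotype_block_mean is None:
            k = _draw_dosages(rng, p, m, dosage_weights)
            hap[:] = rng.random((p, m)).argsort(axis=0) < k[None, :]
        else:
            # ancestry blocks: dosage and carrier set locally constant
            edges = [0]
            while edges[-1] < length:
                edges.append(edges[-1] + max(1, int(rng.exponential(spec.haplotype_block_mean))))
            for b0, b1 in zip(edges[:-1], edges[1:]):
                sel = (pos > b0) & (pos <= b1)
                if not sel.any():
                    continue
                k = int(_draw_dosages(rng, p, 1, dosage_weights)[0])
                carriers = rng.choice(p, size=k, replace=False)
                hap[np.ix_(carriers, np.flatnonzero(sel))] = 1
        ref_idx = rng.integers(0, 4, size=m)
        alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
        positions.append(pos)
        haplotypes.append(hap)
        refs.append(_BASES[ref_idx])
        alts.append(_BASES[alt_idx])
    return ParentGenome(spec, positions, haplotypes, refs, alts)


def parent_cell(parent: ParentGenome, name: str = "parent") -> CellState:
    """The parent itself viewed as a cell (one chromatid per homolog)."""
    chromatids = [
        [parent.haplotypes[c][h].copy() for h in range(parent.spec.ploidy[c])]
        for c in range(parent.spec.n_chroms)
    ]
    return CellState(parent, chromatids, name=name)


def _draw_tract(rng: np.random.Generator, mean: float) -> int:
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / mean))


def simulate_rtg(
    parent: ParentGenome,
    n_dsb_per_Mb: float = 3.0,
    p_crossover: float = 0.5,
    nco_tract_mean: float = 2_000.0,
    co_tract_mean: float = 2_000.0,
    p_missegregation: float = 0.0,
    seed: int = 0,
    forced_cos: tuple[ForcedCrossover, ...] = (),
    hotspots=None,
) -> tuple[CellState, CellState, RTGSimTruth]:
    """Simulate one RTG event: aborted meiosis followed by the first mitosis.

    Each homolog is replicated into two sisters, DSBs are placed as a
    Poisson process (uniform, or weighted by ``hotspots`` — a per-chromosome
    ``(bin_edges, weights)`` intensity track), each DSB picks two chromatids
    of distinct randomly paired homologs (aneuploid extras pair randomly per
    event) and resolves as CO with probability ``p_crossover`` (reciprocal
    swap downstream of the conversion tract) or NCO (one-sided conversion);
    tract lengths are geometric with the given means (the study's gene
    conversions are generally < 2 kbp, hence the defaults). Mother and
    daughter then draw one sister per homolog; with probability
    ``p_missegregation`` one homolog of one chromosome segregates 2:0.

    Returns (mother, daughter, truth), deterministic given ``seed``.
    """
    if n_dsb_per_Mb < 0 or p_missegregation < 0 or not (0 <= p_crossover <= 1):
        raise ValueError("rates must be >= 0 and p_crossover a probability")
    rng = np.random.default_rng(seed)
    spec = parent.spec
    chromatids = []   # per chromosome: array (p, 2, m)
    events: list[RecombinationEvent] = []
    forced_by_chrom: dict[int, list[ForcedCrossover]] = {}
    for fc in forced_cos:
        forced_by_chrom.setdefault(fc.chrom, []).append(fc)

    for c in range(spec.n_chroms):
        p = spec.ploidy[c]
        pos = parent.positions[c]
        m = len(pos)
        tids = np.repeat(parent.haplotypes[c][:, None, :], 2, axis=1).astype(np.int8)

        n_ev = rng.poisson(n_dsb_per_Mb * spec.chrom_lengths[c] / 1e6)
        for _ in range(n_ev):
            if hotspots is not None and hotspots.get(c) is not None:
                edges, weights = hotspots[c]
                b = rng.choice(len(weights), p=np.asarray(weights, float) / np.sum(weights))
                x = int(rng.integers(edges[b], edges[b + 1]))
            else:
                x = int(rng.integers(1, spec.chrom_lengths[c] + 1))
            h1, h2 = rng.choice(p, size=2, replace=False)
            s1, s2 = int(rng.integers(2)), int(rng.integers(2))
            is_co = rng.random() < p_crossover
            tract = _draw_tract(rng, co_tract_mean if is_co else nco_tract_mean)
            _apply_event(tids, pos, x, tract, (h1, h2), (s1, s2), is_co, events, c)
        for fc in forced_by_chrom.get(c, []):
            _apply_event(
                tids, pos, fc.pos, fc.tract_len, fc.homologs, fc.sisters, True, events, c,
                forced=True,
            )
        chromatids.append(tids)

    # segregation: one sister of each homolog to the mother
    sister_to_mother = [rng.integers(0, 2, size=spec.ploidy[c]) for c in range(spec.n_chroms)]
    for fc in forced_cos:
        if fc.split:
            # recombinant chromatids must land in different cells
            sister_to_mother[fc.chrom][fc.homologs[0]] = fc.sisters[0]
            sister_to_mother[fc.chrom][fc.homologs[1]] = 1 - fc.sisters[1]

    missegregation = None
    if rng.random() < p_missegregation:
        mc = int(rng.integers(spec.n_chroms))
        mh = int(rng.integers(spec.ploidy[mc]))
        missegregation = (mc, mh, bool(rng.integers(2)))

    mother_tids, daughter_tids = [], []
    for c in range(spec.n_chroms):
        mt, dt = [], []
        for h in range(spec.ploidy[c]):
            s = int(sister_to_mother[c][h])
            if missegregation is not None and missegregation[0] == c and missegregation[1] == h:
                dest = mt if missegregation[2] else dt
                dest.append(chromatids[c][h, 0].copy())
                dest.append(chromatids[c][h, 1].copy())
            else:
                mt.append(chromatids[c][h, s].copy())
                dt.append(chromatids[c][h, 1 - s].copy())
        mother_tids.append(mt)
        daughter_tids.append(dt)

    mother = CellState(parent, mother_tids, name="mother")
    daughter = CellState(parent, daughter_tids, name="daughter")
    truth = RTGSimTruth(
        parent=parent,
        events=events,
        sister_to_mother=sister_to_mother,
        missegregation=missegregation,
        mother_dosage=[mother.dosage(c) for c in range(spec.n_chroms)],
        daughter_dosage=[daughter.dosage(c) for c in range(spec.n_chroms)],
    )
    return mother, daughter, truth


def _apply_event(tids, pos, x, tract, homologs, sisters, is_co, events, chrom, forced=False):
    (h1, h2), (s1, s2) = homologs, sisters
    if h1 == h2:
        raise ValueError("event homologs must differ")
    tract_end = x + tract
    i0 = int(np.searchsorted(pos, x))
    i1 = int(np.searchsorted(pos, tract_end))
    # one-sided conversion: recipient (h1, s1) copies the donor over the tract
    tids[h1, s1, i0:i1] = tids[h2, s2, i0:i1]
    if is_co:
        j = i1
        tmp = tids[h1, s1, j:].copy()
        tids[h1, s1, j:] = tids[h2, s2, j:]
        tids[h2, s2, j:] = tmp
    events.append(
        RecombinationEvent(
            kind="CO" if is_co else "NCO",
            chrom=chrom,
            pos=int(x),
            tract_end=int(tract_end),
            homologs=(int(h1), int(h2)),
            sisters=(int(s1), int(s2)),
            i_tract=(i0, i1),
            forced=forced,
        )
    )


# ---------------------------------------------------------------------------
# observation layer


def exact_observations(cell: CellState, depth: int = 600) -> pd.DataFrame:
    """Noise-free sample allele table: AF exactly equals dosage / copy number.

    Depths are deterministic (``depth`` reads split in proportion to the
    true allele fraction; 600 divides evenly for ploidies 2-6). Useful as
    the idealised end of the observation model in validation studies.
    """
    parent = cell.parent
    spec = parent.spec
    frames = []
    for c in range(spec.n_chroms):
        p = spec.ploidy[c]
        cn = cell.copy_number(c)
        d = cell.dosage(c)
        alt = (depth * d) // max(cn, 1) if cn else np.zeros(len(d), dtype=int)
        total = depth if cn else 0
        frames.append(
            pd.DataFrame(
                {
                    "chrom": spec.chrom_names[c],
                    "pos": parent.positions[c],
                    "ref": parent.ref_alleles[c],
                    "alt": parent.alt_alleles[c],
                    "k": parent.dosage(c),
                    "p": p,
                    "ref_depth": total - alt,
                    "alt_depth": alt,
                    "gt_k": np.clip(np.rint(d / max(cn, 1) * p), 0, p).astype(int),
                    "qual": 2000.0,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["total_depth"] = table["ref_depth"] + table["alt_depth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        table["af"] = np.where(
            table["total_depth"] > 0, table["alt_depth"] / table["total_depth"], np.nan
        )
    table["in_vcf"] = table["alt_depth"] > 0
    table["status"] = np.where(
        table["total_depth"] > 0,
        np.where(table["in_vcf"], "genotyped_het", "hom_ref_candidate"),
        "missing",
    )
    return table


def emit_observations(
    cell: CellState,
    noise: NoiseModel,
    seed: int = 0,
    sample_name: str = "sample",
    vcf_path=None,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Sample per-marker allele depths for a cell and optionally write a VCF.

    Depth is drawn from the noise model; Alt reads are Binomial(depth, q)
    with q the true Alt fraction of the cell's chromatid complement folded
    with the per-read error rate. A marker enters the VCF when it was not
    dropped out and at least one Alt read was observed (a variant caller
    emits no record at a homozygous-reference position); the emitted GT is
    the true dosage expressed at the catalogue's nominal ploidy, AD/DP carry
    the noisy depths.

    Returns a sample allele table aligned to the parent's marker list with
    columns (chrom, pos, ref, alt, k, p, ref_depth, alt_depth, total_depth,
    af, status, qual); ``status`` follows the joining rule used on real
    files: present -> ``genotyped_het``, absent but sequenced (depth >=
    ``min_depth``) -> ``hom_ref_candidate``, else ``missing``.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    parent = cell.parent
    spec = parent.spec
    frames = []
    for c in range(spec.n_chroms):
        m = len(parent.positions[c])
        p = spec.ploidy[c]
        cn = cell.copy_number(c)
        d = cell.dosage(c)
        if cn == 0:
            depth = np.zeros(m, dtype=int)
            q = np.zeros(m)
        else:
            depth = noise.draw_depth(rng, m)
            f = d / cn
            q = f * (1 - noise.error_rate) + (1 - f) * noise.error_rate
        alt = rng.binomial(depth, q)
        drop = rng.random(m) < noise.dropout
        in_vcf = (~drop) & (depth > 0) & (alt > 0)
        gt_k = np.clip(np.rint(np.where(cn > 0, d / max(cn, 1), 0.0) * p), 0, p).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": spec.chrom_names[c],
                    "pos": parent.positions[c],
                    "ref": parent.ref_alleles[c],
                    "alt": parent.alt_alleles[c],
                    "k": parent.dosage(c),
                    "p": p,
                    "ref_depth": np.where(in_vcf, depth - alt, np.where(drop, 0, depth)),
                    "alt_depth": np.where(in_vcf, alt, 0),
                    "in_vcf": in_vcf,
                    "gt_k": gt_k,
                    "qual": np.minimum(3.0 * depth, 2000.0),
                    "_depth_at_pos": np.where(drop, np.round(noise.mean_depth * cn / p), depth),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["total_depth"] = table["ref_depth"] + table["alt_depth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        table["af"] = np.where(
            table["total_depth"] > 0, table["alt_depth"] / table["total_depth"], np.nan
        )
    table["status"] = np.where(
        table["in_vcf"],
        "genotyped_het",
        np.where(table["_depth_at_pos"] >= min_depth, "hom_ref_candidate", "missing"),
    )
    # a marker absent from the VCF but sequenced is scored as AF 0 downstream
    absent_ok = (~table["in_vcf"]) & (table["status"] == "hom_ref_candidate")
    table.loc[absent_ok & (table["total_depth"] == 0), "total_depth"] = table.loc[
        absent_ok & (table["total_depth"] == 0), "_depth_at_pos"
    ].astype(int)
    table.loc[absent_ok, "af"] = 0.0
    table = table.drop(columns=["_depth_at_pos"])
    if vcf_path is not None:
        write_vcf(table[table["in_vcf"]], spec, sample_name, vcf_path)
    return table


def write_vcf(records: pd.DataFrame, spec: GenomeSpec, sample_name: str, path) -> None:
    """Write marker records as an uncompressed VCF 4.2 with GT:AD:DP."""
    import pysam

    header = pysam.VariantHeader()
    for name, length in zip(spec.chrom_names, spec.chrom_lengths):
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(sample_name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        chrom_order = {n: i for i, n in enumerate(spec.chrom_names)}
        records = records.sort_values(
            ["chrom", "pos"], key=lambda s: s.map(chrom_order) if s.name == "chrom" else s
        )
        for row in records.itertuples(index=False):
            p = int(row.p)
            gt_k = int(row.gt_k)
            rec = out.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                alleles=(str(row.ref), str(row.alt)),
                qual=float(row.qual),
            )
            rec.samples[sample_name]["GT"] = tuple([0] * (p - gt_k) + [1] * gt_k)
            rec.samples[sample_name].phased = False
            rec.samples[sample_name]["AD"] = (int(row.ref_depth), int(row.alt_depth))
            rec.samples[sample_name]["DP"] = int(row.ref_depth) + int(row.alt_depth)
            out.write(rec)


def emit_depth_track(
    cell: CellState,
    noise: NoiseModel,
    window: int = 1_000,
    seed: int = 0,
    cnvs: tuple[tuple[int, int, int, int], ...] = (),
    path=None,
) -> pd.DataFrame:
    """Per-window mean sequencing depth proportional to local copy number.

    Windows are fixed-width, 0-based half-open (chrom, start, end,
    mean_depth). ``mean_depth`` is the genome-wide average at the genome's
    base ploidy, so a window at local chromatid count c sits at expected
    depth ``mean_depth * c / base_ploidy`` — an aneuploid extra copy or a
    planted CNV from ``cnvs`` (tuples ``(chrom_index, start, end,
    copy_delta)``, overlap-weighted) scales it accordingly. Sampling noise
    is Poisson at per-base resolution aggregated over the window.
    Deterministic given ``seed``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rng = np.random.default_rng(seed)
    spec = cell.parent.spec
    rows = []
    p = spec.base_ploidy
    for c in range(spec.n_chroms):
        length = spec.chrom_lengths[c]
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        cn = np.full(len(starts), float(cell.copy_number(c)))
        for cc, s, e, delta in cnvs:
            if cc != c:
                continue
            ov = np.maximum(0, np.minimum(ends, e) - np.maximum(starts, s))
            cn = cn + delta * ov / (ends - starts)
        lam = noise.mean_depth * cn / p * (ends - starts)
        tot = rng.poisson(np.maximum(lam, 0.0))
        rows.append(
            pd.DataFrame(
                {
                    "chrom": spec.chrom_names[c],
                    "start": starts,
                    "end": ends,
                    "mean_depth": tot / (ends - starts),
                }
            )
        )
    track = pd.concat(rows, ignore_index=True)
    if path is not None:
        track.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return track


def write_truth_bed(truth: RTGSimTruth, cell: str, path) -> pd.DataFrame:
    """True dosage-shift tracts of one cell as BED (0-based half-open).

    Columns: chrom, start, end, n_markers, direction, event_kinds (comma
    list of CO/NCO events whose tract or downstream segment overlaps).
    """
    tracts = truth.shift_tracts(cell)
    kinds = []
    names = truth.parent.spec.chrom_names
    for row in tracts.itertuples(index=False):
        ks = sorted(
            {
                ev.kind
                for ev in truth.events
                if names[ev.chrom] == row.chrom
                and (ev.kind == "CO" and ev.pos <= row.end or ev.pos - 1 < row.end and ev.tract_end > row.start)
            }
        )
        kinds.append(",".join(ks) if ks else ".")
    out = tracts[["chrom", "start", "end", "n_markers", "direction"]].copy()
    out["event_kinds"] = kinds
    out.to_csv(path, sep="\t", index=False, header=False)
    return out
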