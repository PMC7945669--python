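"""BEAST2 skyline XML generation and run-output post-processing.

:func:`setup_basic_xml` writes a self-contained BEAST2 input document for a
coalescent Bayesian-skyline analysis: the cleaned alignment, an HKY (or
user-chosen) site model, a strict clock at a user-supplied mutation rate,
the skyline tree prior, and trace/tree loggers.  Keeping every species on
the same skeleton, differing only in the fields that must differ, is what
makes a multi-species comparison honest.

After a run, :func:`effective_sample_size` estimates the number of
effectively independent MCMC samples per parameter (values below 200 are
flagged as unreliable), and :func:`parse_skyline_summary` loads a
Tracer-style skyline export for plotting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from lxml import etree

from .alignment import Alignment
from .core import logger

PathLike = Union[str, Path]

#: MCMC outputs with fewer effectively independent samples than this are
#: conventionally treated with caution.
ESS_THRESHOLD = 200.0


@dataclass
class BeastRunConfig:
    """Per-dataset knobs of the skyline XML skeleton."""

    mutation_rate: float  # substitutions / site / year (strict clock)
    output_stem: str
    chain_length: int = 10_000_000
    log_every: int = 1000
    skyline_groups: int = 5
    substitution_model: str = "HKY"

    def __post_init__(self) -> None:
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be > 0")
        if self.chain_length <= 0:
            raise ValueError("chain_length must be > 0")
        if self.skyline_groups < 1:
            raise ValueError("skyline_groups must be >= 1")
        if self.log_every <= 0:
            raise ValueError("log_every must be > 0")
        if self.substitution_model not in ("HKY", "JC69", "GTR"):
            raise ValueError(
                f"unsupported substitution model {self.substitution_model!r}"
            )
        if not re.fullmatch(r"[\w.\-]+", self.output_stem):
            raise ValueError(f"unsafe output stem {self.output_stem!r}")


@dataclass
class TraceSeries:
    """One logged MCMC parameter after burn-in removal."""

    name: str
    values: np.ndarray
    burn_in: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in fraction must be in [0, 1)")
        self.values = np.asarray(self.values, dtype=float)

    @classmethod
    def from_raw(
        cls, name: str, raw_values, burn_in: float = 0.1
    ) -> "TraceSeries":
        """Discard the first ``burn_in`` fraction of a raw trace."""
        raw = np.asarray(raw_values, dtype=float)
        if not 0 <= burn_in < 1:
            raise ValueError("burn_in fraction must be in [0, 1)")
        start = int(len(raw) * burn_in)
        return cls(name=name, values=raw[start:], burn_in=burn_in)


@dataclass
class SkylineProfile:
    """Median Ne and 95% HPD bounds through time (years before present)."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["time", "median", "lower", "upper"]
        )
    )

    def __post_init__(self) -> None:
        t = self.table
        if len(t):
            bad = t.index[(t["lower"] > t["median"]) | (t["median"] > t["upper"])]
            if len(bad):
                raise ValueError(
                    f"HPD bounds do not bracket the median in row {bad[0] + 1}"
                )
            times = t["time"].to_numpy()
            if not np.all(np.diff(times) > 0):
                raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.table)


_NSMAP = (
    "beast.core:beast.evolution.alignment:beast.evolution.tree.coalescent:"
    "beast.core.util:beast.evolution.nuc:beast.evolution.operators:"
    "beast.evolution.sitemodel:beast.evolution.substitutionmodel:"
    "beast.evolution.likelihood"
)


def setup_basic_xml(aln: Alignment, cfg: BeastRunConfig) -> str:
    """Build a BEAST2 Bayesian-skyline XML document as a string.

    The alignment must be the cleaned pipeline product: rectangular,
    gap-free and unambiguous.  Sequences, taxon labels, the clock rate and
    the chain length are embedded verbatim and are recoverable from the
    document (see the ``extract_*`` helpers).
    """
    if not aln.matrix:
        raise ValueError("empty alignment")
    if not aln.is_clean():
        raise ValueError(
            "alignment still contains gaps or ambiguity codes; run the "
            "crop/clean steps before XML generation"
        )
    beast = etree.Element(
        "beast",
        attrib={"version": "2.6", "namespace": _NSMAP},
    )
    data = etree.SubElement(
        beast, "data", attrib={"id": "alignment", "dataType": "nucleotide", "name": "alignment"}
    )
    for sid, row in zip(aln.seq_ids, aln.matrix):
        etree.SubElement(
            data,
            "sequence",
            attrib={
                "id": f"seq_{sid}",
                "taxon": sid,
                "totalcount": "4",
                "value": row,
            },
        )
    run = etree.SubElement(
        beast,
        "run",
        attrib={
            "id": "mcmc",
            "spec": "MCMC",
            "chainLength": str(cfg.chain_length),
        },
    )
    state = etree.SubElement(run, "state", attrib={"id": "state", "storeEvery": "5000"})
    tree = etree.SubElement(
        state, "tree", attrib={"id": "Tree.t", "name": "stateNode"}
    )
    taxa = etree.SubElement(
        tree, "taxonset", attrib={"id": "TaxonSet.alignment", "spec": "TaxonSet"}
    )
    etree.SubElement(taxa, "alignment", attrib={"idref": "alignment"})
    pop = etree.SubElement(
        state,
        "parameter",
        attrib={
            "id": "bPopSizes",
            "name": "stateNode",
            "dimension": str(cfg.skyline_groups),
            "lower": "0.0",
        },
    )
    pop.text = "380.0"
    groups = etree.SubElement(
        state,
        "stateNode",
        attrib={
            "id": "bGroupSizes",
            "spec": "parameter.IntegerParameter",
            "dimension": str(cfg.skyline_groups),
        },
    )
    groups.text = "1"
    if cfg.substitution_model in ("HKY", "GTR"):
        kappa = etree.SubElement(
            state,
            "parameter",
            attrib={"id": "kappa", "name": "stateNode", "lower": "0.0"},
        )
        kappa.text = "2.0"

    etree.SubElement(
        run,
        "init",
        attrib={
            "id": "RandomTree.t",
            "spec": "beast.evolution.tree.RandomTree",
            "estimate": "false",
            "initial": "@Tree.t",
            "taxa": "@alignment",
        },
    )
    posterior = etree.SubElement(
        run,
        "distribution",
        attrib={"id": "posterior", "spec": "util.CompoundDistribution"},
    )
    prior = etree.SubElement(
        posterior,
        "distribution",
        attrib={"id": "prior", "spec": "util.CompoundDistribution"},
    )
    skyline = etree.SubElement(
        prior,
        "distribution",
        attrib={
            "id": "BayesianSkyline.t",
            "spec": "BayesianSkyline",
            "groupSizes": "@bGroupSizes",
            "popSizes": "@bPopSizes",
        },
    )
    etree.SubElement(
        skyline,
        "treeIntervals",
        attrib={"id": "TreeIntervals.t", "spec": "TreeIntervals", "tree": "@Tree.t"},
    )
    etree.SubElement(
        prior,
        "distribution",
        attrib={
            "id": "MarkovChainedPopSizes.t",
            "spec": "beast.math.distributions.MarkovChainDistribution",
            "jeffreys": "true",
            "parameter": "@bPopSizes",
        },
    )
    likelihood = etree.SubElement(
        posterior,
        "distribution",
        attrib={"id": "likelihood", "spec": "util.CompoundDistribution"},
    )
    tl = etree.SubElement(
        likelihood,
        "distribution",
        attrib={
            "id": "treeLikelihood",
            "spec": "ThreadedTreeLikelihood",
            "data": "@alignment",
            "tree": "@Tree.t",
        },
    )
    site = etree.SubElement(
        tl,
        "siteModel",
        attrib={"id": "SiteModel.s", "spec": "SiteModel"},
    )
    if cfg.substitution_model == "HKY":
        subst = etree.SubElement(
            site,
            "substModel",
            attrib={"id": "hky", "spec": "HKY", "kappa": "@kappa"},
        )
        freqs = etree.SubElement(
            subst,
            "frequencies",
            attrib={"id": "empiricalFreqs", "spec": "Frequencies", "data": "@alignment"},
        )
        del freqs
    elif cfg.substitution_model == "JC69":
        etree.SubElement(
            site,
            "substModel",
            attrib={"id": "jc69", "spec": "JukesCantor"},
        )
    else:  # GTR
        subst = etree.SubElement(
            site,
            "substModel",
            attrib={"id": "gtr", "spec": "GTR"},
        )
        etree.SubElement(
            subst,
            "frequencies",
            attrib={"id": "empiricalFreqs", "spec": "Frequencies", "data": "@alignment"},
        )
    clock = etree.SubElement(
        tl,
        "branchRateModel",
        attrib={
            "id": "StrictClock.c",
            "spec": "beast.evolution.branchratemodel.StrictClockModel",
        },
    )
    rate = etree.SubElement(
        clock,
        "parameter",
        attrib={
            "id": "clockRate.c",
            "name": "clock.rate",
            "estimate": "false",
        },
    )
    rate.text = repr(cfg.mutation_rate)

    for op_id, spec, extra in [
        ("treeScaler", "ScaleOperator", {"scaleFactor": "0.5", "tree": "@Tree.t", "weight": "3.0"}),
        ("treeRootScaler", "ScaleOperator", {"rootOnly": "true", "scaleFactor": "0.5", "tree": "@Tree.t", "weight": "3.0"}),
        ("uniformOperator", "Uniform", {"tree": "@Tree.t", "weight": "30.0"}),
        ("subtreeSlide", "SubtreeSlide", {"tree": "@Tree.t", "weight": "15.0"}),
        ("narrow", "Exchange", {"tree": "@Tree.t", "weight": "15.0"}),
        ("wide", "Exchange", {"isNarrow": "false", "tree": "@Tree.t", "weight": "3.0"}),
        ("WilsonBalding", "WilsonBalding", {"tree": "@Tree.t", "weight": "3.0"}),
        ("popSizesScaler", "ScaleOperator", {"parameter": "@bPopSizes", "scaleFactor": "0.75", "weight": "15.0"}),
        ("groupSizesDelta", "DeltaExchangeOperator", {"integer": "true", "weight": "6.0"}),
    ]:
        op = etree.SubElement(
            run, "operator", attrib={"id": op_id, "spec": spec, **extra}
        )
        if op_id == "groupSizesDelta":
            etree.SubElement(op, "intparameter", attrib={"idref": "bGroupSizes"})
    if cfg.substitution_model in ("HKY", "GTR"):
        etree.SubElement(
            run,
            "operator",
            attrib={
                "id": "kappaScaler",
                "spec": "ScaleOperator",
                "parameter": "@kappa",
                "scaleFactor": "0.5",
                "weight": "0.1",
            },
        )

    tracelog = etree.SubElement(
        run,
        "logger",
        attrib={
            "id": "tracelog",
            "fileName": f"{cfg.output_stem}.log",
            "logEvery": str(cfg.log_every),
            "model": "@posterior",
        },
    )
    for ref in ("posterior", "likelihood", "prior", "BayesianSkyline.t", "bPopSizes", "bGroupSizes"):
        etree.SubElement(tracelog, "log", attrib={"idref": ref})
    screenlog = etree.SubElement(
        run, "logger", attrib={"id": "screenlog", "logEvery": str(cfg.log_every)}
    )
    etree.SubElement(screenlog, "log", attrib={"idref": "posterior"})
    treelog = etree.SubElement(
        run,
        "logger",
        attrib={
            "id": "treelog",
            "fileName": f"{cfg.output_stem}.trees",
            "logEvery": str(cfg.log_every),
            "mode": "tree",
        },
    )
    etree.SubElement(treelog, "log", attrib={"idref": "Tree.t"})

    return etree.tostring(
        beast, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


def write_xml(aln: Alignment, cfg: BeastRunConfig, path: PathLike) -> None:
    Path(path).write_text(setup_basic_xml(aln, cfg))


# -- extraction helpers (round-trip checks and downstream tooling) ----------

def extract_sequences(xml_text: str) -> dict[str, str]:
    root = etree.fromstring(xml_text.encode())
    return {
        el.get("taxon"): el.get("value")
        for el in root.findall(".//data/sequence")
    }


def extract_clock_rate(xml_text: str) -> float:
    root = etree.fromstring(xml_text.encode())
    el = root.find(".//parameter[@name='clock.rate']")
    if el is None:
        raise ValueError("no clock.rate parameter in document")
    return float(el.text)


def extract_chain_length(xml_text: str) -> int:
    root = etree.fromstring(xml_text.encode())
    run = root.find("run")
    if run is None:
        raise ValueError("no run element in document")
    return int(run.get("chainLength"))


def extract_skyline_groups(xml_text: str) -> int:
    root = etree.fromstring(xml_text.encode())
    el = root.find(".//parameter[@id='bPopSizes']")
    if el is None:
        raise ValueError("no skyline population-size parameter in document")
    return int(el.get("dimension"))


def extract_output_stem(xml_text: str) -> str:
    root = etree.fromstring(xml_text.encode())
    el = root.find(".//logger[@id='tracelog']")
    if el is None:
        raise ValueError("no tracelog logger in document")
    return re.sub(r"\.log$", "", el.get("fileName"))


# -- ESS -------------------------------------------------------------------

def _autocovariance(x: np.ndarray) -> np.ndarray:
    n = len(x)
    x = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    return acov / n


def effective_sample_size(tr: TraceSeries) -> float:
    """Effective sample size by the initial-positive-sequence rule.

    ESS = n / (1 + 2 Σ ρ̂_k), where the autocorrelations ρ̂_k are summed in
    adjacent pairs Γ_m = ρ̂_{2m} + ρ̂_{2m+1} for as long as the pair sums stay
    positive (Geyer's initial positive sequence).  A constant series returns
    1 by convention.  Results below 200 are logged as unreliable.
    """
    x = tr.values
    n = len(x)
    if n < 10:
        raise ValueError(f"need >= 10 samples for an ESS estimate, got {n}")
    acov = _autocovariance(x)
    if np.all(x == x[0]) or acov[0] <= 0 or not np.isfinite(acov[0]):
        ess = 1.0  # constant (or degenerate) series
    else:
        rho = acov / acov[0]
        tau = -1.0
        m = 0
        while 2 * m + 1 < n:
            gamma = rho[2 * m] + rho[2 * m + 1]
            if gamma <= 0:
                break
            tau += 2.0 * gamma
            m += 1
        ess = float(min(n, max(1.0, n / max(tau, 1e-12))))
    if ess < ESS_THRESHOLD:
        logger.warning(
            "effective_sample_size: %s ESS %.1f is below %d; treat with caution",
            tr.name,
            ess,
            int(ESS_THRESHOLD),
        )
    return ess


def low_ess_parameters(
    traces: list[TraceSeries], threshold: float = ESS_THRESHOLD
) -> list[tuple[str, float]]:
    """(name, ESS) pairs whose ESS falls below ``threshold``."""
    out = []
    for tr in traces:
        ess = effective_sample_size(tr)
        if ess < threshold:
            out.append((tr.name, ess))
    return out


def read_trace_log(path: PathLike, burn_in: float = 0.1) -> list[TraceSeries]:
    """Read a BEAST trace log (tab-delimited, '#' comments) into series."""
    df = pd.read_csv(path, sep="\t", comment="#")
    sample_cols = [c for c in df.columns if c.lower() in ("sample", "state")]
    series = []
    for col in df.columns:
        if col in sample_cols:
            continue
        series.append(TraceSeries.from_raw(col, df[col].to_numpy(), burn_in))
    return series


# -- skyline summaries -----------------------------------------------------

_COLUMN_ALIASES = {
    "time": ("time", "age", "time (years)"),
    "median": ("median", "med"),
    "lower": ("lower", "lower 95% hpd", "hpd lower 95", "95% hpd lower"),
    "upper": ("upper", "upper 95% hpd", "hpd upper 95", "95% hpd upper"),
}


def _match_columns(columns) -> dict[str, str]:
    resolved = {}
    lowered = {str(c).strip().lower(): c for c in columns}
    for want, aliases in _COLUMN_ALIASES.items():
        found = None
        for alias in aliases:
            if alias in lowered:
                found = lowered[alias]
                break
        if found is None:
            for low, orig in lowered.items():
                if want in low:
                    found = orig
                    break
        if found is None:
            raise ValueError(f"skyline summary is missing a {want!r} column")
        resolved[want] = found
    return resolved


def parse_skyline_summary(path: PathLike) -> SkylineProfile:
    """Load a Tracer-style skyline export (tab or comma delimited)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.empty:
        logger.warning("parse_skyline_summary: %s holds a header but no rows", path)
        return SkylineProfile()
    cols = _match_columns(df.columns)
    table = pd.DataFrame(
        {
            "time": pd.to_numeric(df[cols["time"]]),
            "median": pd.to_numeric(df[cols["median"]]),
            "lower": pd.to_numeric(df[cols["lower"]]),
            "upper": pd.to_numeric(df[cols["upper"]]),
        }
    ).reset_index(drop=True)
    return SkylineProfile(table=table)


def write_skyline_summary(profile: SkylineProfile, path: PathLike) -> None:
    profile.table.to_csv(path, sep="\t", index=False)


def plot_skyline(profile: SkylineProfile, path: PathLike) -> None:
    """Median Ne (dashed) with the 95% HPD envelope shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = profile.table
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(t["time"], t["lower"], t["upper"], alpha=0.3, label="95% HPD")
    ax.plot(t["time"], t["median"], linestyle="--", color="black", label="median Ne")
    ax.set_xlabel("Time before present (years)")
    ax.set_ylabel("Effective population size")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
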