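"""TSV writers with self-describing comment headers.

Every output records the full parameter set, a short config hash, the
software version and any seeds, so scan tables are reproducible
bit-for-bit from their own headers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .analytic import DiscretePMF, MomentSummary
from .cme import PromoterResolvedPMF
from .params import GeneModelParams


def _header_lines(params: GeneModelParams | None, extra: dict | None = None) -> list[str]:
    from . import __version__

    lines = [f"# leaky-telegraph {__version__}"]
    if params is not None:
        for key, value in params.as_dict().items():
            lines.append(f"# {key}: {value!r}")
        lines.append(f"# config_hash: {params.config_hash()}")
    for key, value in (extra or {}).items():
        lines.append(f"# {key}: {value}")
    return lines


def write_distribution(path: str | Path, pmf: DiscretePMF,
                       extra: dict | None = None) -> None:
    """Two-column TSV (n, probability) with a comment header."""
    meta = {"source": pmf.source, "support_max": pmf.support_max,
            "renorm_residual": f"{pmf.renorm_residual:.3e}"}
    meta.update(extra or {})
    lines = _header_lines(pmf.params, meta)
    lines.append("n\tprobability")
    for n, p in enumerate(pmf.probs):
        lines.append(f"{n}\t{p:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_promoter_resolved(path: str | Path, pmf: PromoterResolvedPMF) -> None:
    """Three-column TSV (n, P0, P1) of the promoter-resolved law."""
    lines = _header_lines(pmf.params, {"support_max": pmf.support_max})
    lines.append("n\tP0\tP1")
    for n, (a, b) in enumerate(zip(pmf.p0, pmf.p1)):
        lines.append(f"{n}\t{a:.17g}\t{b:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_moments(path: str | Path, m: MomentSummary,
                  params: GeneModelParams | None = None) -> None:
    """Single-row TSV of the moment summary."""
    lines = _header_lines(params)
    lines.append("mean\tvariance\tnoise\tgprime\tgdoubleprime")
    lines.append(
        f"{m.mean:.17g}\t{m.variance:.17g}\t{m.noise:.17g}\t"
        f"{m.gprime:.17g}\t{m.gdoubleprime:.17g}"
    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_scan(path: str | Path, table: pd.DataFrame,
               params: GeneModelParams | None = None,
               seeds: Iterable[int] | None = None,
               extra: dict | None = None) -> None:
    """Scan table as TSV under a reproducibility header."""
    meta = dict(extra or {})
    if seeds is not None:
        meta["seeds"] = ",".join(str(s) for s in seeds)
    lines = _header_lines(params, meta)
    body = table.to_csv(sep="\t", index=False)
    Path(path).write_text("\n".join(lines) + "\n" + body)


def write_trajectory(path: str | Path, traj) -> None:
    """Trajectory as TSV (time, promoter_state, count[, mrna])."""
    meta = {"seed": traj.seed, "variant": traj.variant, "t_end": traj.t_end}
    lines = _header_lines(traj.params, meta)
    cols = {"time": traj.times, "promoter_state": traj.promoter_states,
            "count": traj.counts}
    if traj.mrna is not None:
        cols["mrna"] = traj.mrna
    body = pd.DataFrame(cols).to_csv(sep="\t", index=False, float_format="%.10g")
    Path(path).write_text("\n".join(lines) + "\n" + body)
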