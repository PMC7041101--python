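"""Dot-plot export: one segment per reported region alignment.

The tab-separated table carries the segment endpoints (query on x,
reference on y); forward-strand regions are positive-slope diagonals and
reverse-strand regions negative-slope (their query coordinates are mapped
back to the forward frame for plotting).  An optional PNG rendering uses
matplotlib.
"""

from __future__ import annotations

from .fmindex import REVERSE

_COLUMNS = (
    "query",
    "q_start",
    "q_end",
    "reference",
    "r_start",
    "r_end",
    "strand",
)


def _segments(result, query_lengths: dict[str, int]):
    for ra in result.regions:
        q1, q2 = ra.region.q_start, ra.region.q_end
        if ra.strand == REVERSE:
            qlen = query_lengths[ra.query_name]
            # map reverse-frame coords back to the forward query axis
            q1, q2 = qlen - q1 + 1, qlen - q2 + 1
        yield (
            ra.query_name,
            q1,
            q2,
            ra.ref_name,
            ra.region.p_start,
            ra.region.p_end,
            ra.strand,
        )


def export_dotplot(result, sink, query_lengths: dict[str, int] | None = None,
                   png_path=None) -> list[tuple]:
    """Write segment endpoints as TSV; optionally render a PNG."""
    if query_lengths is None:
        query_lengths = {}
        for ra in result.regions:
            if ra.strand == REVERSE and ra.query_name not in query_lengths:
                raise ValueError(
                    "query_lengths required when reverse-strand regions are present"
                )
    rows = list(_segments(result, query_lengths))
    sink.write("\t".join(_COLUMNS) + "\n")
    for row in rows:
        sink.write("\t".join(str(x) for x in row) + "\n")

    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        for _, q1, q2, _, r1, r2, strand in rows:
            ax.plot([q1, q2], [r1, r2], color="tab:blue" if strand == "+" else "tab:red")
        ax.set_xlabel("query position")
        ax.set_ylabel("reference position")
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return rows
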