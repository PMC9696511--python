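"""Published best-cell metric values for the six kernel x CV-scheme cells,
frozen for ranking-reproduction tests (stage order: training, testing, overall;
metric order: MARDP %, MADP degC, RMSE degC, R-value)."""

from polysol.evaluation import MetricReport, Metrics

_RAW = {
    ("linear", "loo"): [
        (19.15, 25.15, 35.81, 0.1726),
        (27.73, 29.74, 43.63, -0.1032),
        (20.44, 25.84, 37.10, 0.1161),
    ],
    ("polynomial", "loo"): [
        (10.50, 13.73, 20.02, 0.8538),
        (11.20, 15.79, 22.68, 0.7738),
        (10.61, 14.04, 20.44, 0.8386),
    ],
    ("gaussian", "loo"): [
        (8.44, 11.14, 16.99, 0.9234),
        (9.70, 15.35, 18.92, 0.8455),
        (8.63, 11.78, 17.30, 0.9148),
    ],
    ("linear", "kfold10"): [
        (20.52, 26.82, 37.62, 0.1506),
        (20.68, 20.85, 34.09, -0.0893),
        (20.54, 25.92, 37.10, 0.1133),
    ],
    ("polynomial", "kfold10"): [
        (15.68, 18.34, 28.11, 0.6236),
        (14.37, 19.93, 28.19, 0.8333),
        (15.48, 18.58, 28.13, 0.6661),
    ],
    ("gaussian", "kfold10"): [
        (8.35, 11.00, 17.04, 0.9118),
        (7.25, 13.78, 20.93, 0.8624),
        (8.18, 11.42, 17.69, 0.9037),
    ],
}


def published_reports(scheme: str | None = None) -> list[MetricReport]:
    reports = []
    for (kernel, sch), rows in _RAW.items():
        if scheme is not None and sch != scheme:
            continue
        reports.append(MetricReport(
            label=f"{kernel}+{sch}",
            training=Metrics(*rows[0]),
            testing=Metrics(*rows[1]),
            overall=Metrics(*rows[2]),
        ))
    return reports
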