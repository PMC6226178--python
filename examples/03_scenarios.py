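"""One-way scenario analysis.

Re-evaluates the deterministic model varying, one at a time: the post-event
disutility reduction r (0 .. 1), the post-event annual cost fraction f
(10% / 15% / 20% of the acute admission cost), and the discount rate
(5% base, 3.5% alternative). Life-year differences are invariant to all of
these; only incremental QALYs and costs respond.
"""

import cvdcheck as cv

config = cv.load_config()
grid = cv.run_scenario_grid(config)

cols = ["scenario", "sex", "diff_ly", "diff_qaly", "diff_cost",
        "cost_per_ly", "cost_per_qaly"]
out = grid[cols].copy()
out[["diff_ly", "diff_qaly"]] = out[["diff_ly", "diff_qaly"]].round(3)
out[["diff_cost", "cost_per_ly", "cost_per_qaly"]] = (
    out[["diff_cost", "cost_per_ly", "cost_per_qaly"]].round(0)
)
print(out.to_string(index=False))

# Expected directions: $/QALY rises with r (less lifelong disutility averted),
# falls with f (more downstream cost averted), and falls at 3.5% discounting
# (future QALY gains count for more).
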