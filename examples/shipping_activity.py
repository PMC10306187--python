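"""Extract port-zone shipping activity from synthetic route-density rasters.

Builds monthly corridor rasters for 2021 and 2022 in which one port's
activity is blacked out from February to June 2022, extracts 20-km buffer
means per port and month, and prints cumulative series and the
year-on-year percent change at the last common month.
"""

from geoseason import PortZone, cumulative_by_year, monthly_series, percent_change
from geoseason.simulate import simulate_shipping

ports = [PortZone("Odesa", 30.74, 46.50), PortZone("Constanta", 28.74, 44.07)]
months = [f"2021-{m:02d}-01" for m in range(1, 13)] + [f"2022-{m:02d}-01" for m in range(1, 9)]
stack = simulate_shipping(
    months, ports, [("Odesa", "Constanta", 5.0, 15.0)],
    blackout_window=("2022-02-01", "2022-06-30"), blackout_ports=("Odesa",),
    seed=31, grid=(28.0, 32.0, 43.5, 47.0), cellsize=0.05,
)

series = cumulative_by_year(monthly_series(stack, ports))
print("cumulative route density, 2022 (blackout Feb-Jun at Odesa):")
for port in ("Odesa", "Constanta"):
    sub = series[(series["port"] == port) & (series["year"] == 2022)]
    vals = " ".join(f"{v:6.2f}" for v in sub["cumulative"])
    print(f"  {port:10s} {vals}")

for port in ("Odesa", "Constanta"):
    pct = percent_change(series, port, 2021, 2022)
    print(f"percent change to August, 2021 -> 2022, {port}: {pct:+.1f}%")
print("\nThe Odesa series is flat through the blackout window and ends the")
print("season far below 2021; the unaffected port changes only by noise.")
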