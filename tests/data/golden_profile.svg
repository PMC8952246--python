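<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="424.00" height="394.00" viewBox="0 0 424.00 394.00">

<rect x="52.00" y="52.00" width="320.00" height="260.00" fill="none" stroke="#333333"/>
<text x="212.00" y="44.00" text-anchor="middle" font-size="12" class="panel-title">all</text>
<line x1="132.00" y1="312.00" x2="132.00" y2="316.00" stroke="#333333"/>
<text x="132.00" y="328.00" text-anchor="middle" font-size="10" class="x-tick-label">ctrl</text>
<line x1="292.00" y1="312.00" x2="292.00" y2="316.00" stroke="#333333"/>
<text x="292.00" y="328.00" text-anchor="middle" font-size="10" class="x-tick-label">cold</text>
<polyline points="132.00,231.81 292.00,112.16" fill="none" stroke="#1f77b4" stroke-width="1.5" class="series-line" data-entity="g1"/>
<circle cx="132.00" cy="231.81" r="2.50" fill="#1f77b4"/>
<line x1="132.00" y1="255.98" x2="132.00" y2="207.64" stroke="#000000" class="error-bar"/>
<line x1="129.00" y1="255.98" x2="135.00" y2="255.98" stroke="#000000" class="error-bar-cap"/>
<line x1="129.00" y1="207.64" x2="135.00" y2="207.64" stroke="#000000" class="error-bar-cap"/>
<circle cx="292.00" cy="112.16" r="2.50" fill="#1f77b4"/>
<line x1="292.00" y1="160.51" x2="292.00" y2="63.82" stroke="#000000" class="error-bar"/>
<line x1="289.00" y1="160.51" x2="295.00" y2="160.51" stroke="#000000" class="error-bar-cap"/>
<line x1="289.00" y1="63.82" x2="295.00" y2="63.82" stroke="#000000" class="error-bar-cap"/>
<polyline points="132.00,300.18 292.00,283.09" fill="none" stroke="#ff7f0e" stroke-width="1.5" class="series-line" data-entity="g2"/>
<circle cx="132.00" cy="300.18" r="2.50" fill="#ff7f0e"/>
<line x1="132.00" y1="300.18" x2="132.00" y2="300.18" stroke="#000000" class="error-bar"/>
<line x1="129.00" y1="300.18" x2="135.00" y2="300.18" stroke="#000000" class="error-bar-cap"/>
<line x1="129.00" y1="300.18" x2="135.00" y2="300.18" stroke="#000000" class="error-bar-cap"/>
<circle cx="292.00" cy="283.09" r="2.50" fill="#ff7f0e"/>
<line x1="292.00" y1="283.09" x2="292.00" y2="283.09" stroke="#000000" class="error-bar"/>
<line x1="289.00" y1="283.09" x2="295.00" y2="283.09" stroke="#000000" class="error-bar-cap"/>
<line x1="289.00" y1="283.09" x2="295.00" y2="283.09" stroke="#000000" class="error-bar-cap"/>
<text x="46.00" y="315.00" text-anchor="end" font-size="9" class="y-tick-label">0.309</text>
<text x="46.00" y="185.00" text-anchor="end" font-size="9" class="y-tick-label">7.91</text>
<text x="46.00" y="55.00" text-anchor="end" font-size="9" class="y-tick-label">15.5</text>
<text x="14.00" y="182.00" font-size="11" class="y-axis-label" transform="rotate(-90 14 182.00)" text-anchor="middle">expression [TPM]</text>
</svg>
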