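<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="480.00" height="348.00" viewBox="0 0 480.00 348.00">

<text x="40.00" y="46.00" font-size="10" class="area-label">light reactions</text>
<text x="40.00" y="156.00" font-size="10" class="area-label">Calvin cycle</text>
<text x="260.00" y="46.00" font-size="10" class="area-label">photorespiration</text>
<rect x="40.00" y="50.00" width="8.00" height="8.00" fill="#b2182b" stroke="#555555" stroke-width="0.4" class="gene-box" data-gene-id="up" data-value="2" data-description=""/>
<rect x="40.00" y="160.00" width="8.00" height="8.00" fill="#2166ac" stroke="#555555" stroke-width="0.4" class="gene-box" data-gene-id="down" data-value="-2" data-description=""/>
<rect x="348.00" y="12.00" width="5.00" height="10.00" fill="#2a6caf" class="legend-cell"/>
<rect x="353.00" y="12.00" width="5.00" height="10.00" fill="#3d79b6" class="legend-cell"/>
<rect x="358.00" y="12.00" width="5.00" height="10.00" fill="#4f86bd" class="legend-cell"/>
<rect x="363.00" y="12.00" width="5.00" height="10.00" fill="#6293c4" class="legend-cell"/>
<rect x="368.00" y="12.00" width="5.00" height="10.00" fill="#749fcb" class="legend-cell"/>
<rect x="373.00" y="12.00" width="5.00" height="10.00" fill="#87acd2" class="legend-cell"/>
<rect x="378.00" y="12.00" width="5.00" height="10.00" fill="#99b9d9" class="legend-cell"/>
<rect x="383.00" y="12.00" width="5.00" height="10.00" fill="#acc6e0" class="legend-cell"/>
<rect x="388.00" y="12.00" width="5.00" height="10.00" fill="#bed2e7" class="legend-cell"/>
<rect x="393.00" y="12.00" width="5.00" height="10.00" fill="#d1dfee" class="legend-cell"/>
<rect x="398.00" y="12.00" width="5.00" height="10.00" fill="#e3ecf5" class="legend-cell"/>
<rect x="403.00" y="12.00" width="5.00" height="10.00" fill="#f6f9fc" class="legend-cell"/>
<rect x="408.00" y="12.00" width="5.00" height="10.00" fill="#fcf5f6" class="legend-cell"/>
<rect x="413.00" y="12.00" width="5.00" height="10.00" fill="#f5e2e4" class="legend-cell"/>
<rect x="418.00" y="12.00" width="5.00" height="10.00" fill="#efcfd3" class="legend-cell"/>
<rect x="423.00" y="12.00" width="5.00" height="10.00" fill="#e9bcc1" class="legend-cell"/>
<rect x="428.00" y="12.00" width="5.00" height="10.00" fill="#e2a8b0" class="legend-cell"/>
<rect x="433.00" y="12.00" width="5.00" height="10.00" fill="#dc959e" class="legend-cell"/>
<rect x="438.00" y="12.00" width="5.00" height="10.00" fill="#d5828c" class="legend-cell"/>
<rect x="443.00" y="12.00" width="5.00" height="10.00" fill="#cf6f7a" class="legend-cell"/>
<rect x="448.00" y="12.00" width="5.00" height="10.00" fill="#c85b69" class="legend-cell"/>
<rect x="453.00" y="12.00" width="5.00" height="10.00" fill="#c24857" class="legend-cell"/>
<rect x="458.00" y="12.00" width="5.00" height="10.00" fill="#bc3546" class="legend-cell"/>
<rect x="463.00" y="12.00" width="5.00" height="10.00" fill="#b52234" class="legend-cell"/>
<text x="348.00" y="33.00" font-size="9" class="legend-label">-2</text>
<text x="468.00" y="33.00" font-size="9" text-anchor="end" class="legend-label">2</text>
<text x="10.00" y="338.00" font-size="10" class="summary-strip">n=2  min=-2  Q1=-1  median=0  Q3=1  max=2  unassigned=1  excluded=1</text>
</svg>
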