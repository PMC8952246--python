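<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="312.00" height="178.00" viewBox="0 0 312.00 178.00">

<rect x="110.00" y="20.00" width="18.00" height="18.00" fill="#ff2121" class="heat-cell" data-row="s0" data-col="s0" data-value="1"/>
<rect x="128.00" y="20.00" width="18.00" height="18.00" fill="#5a8dff" class="heat-cell" data-row="s0" data-col="s1" data-value="-0.739852"/>
<rect x="146.00" y="20.00" width="18.00" height="18.00" fill="#ffa7a7" class="heat-cell" data-row="s0" data-col="s3" data-value="0.395652"/>
<rect x="164.00" y="20.00" width="18.00" height="18.00" fill="#fff3f3" class="heat-cell" data-row="s0" data-col="s2" data-value="0.0521804"/>
<text x="186.00" y="32.60" font-size="10" class="row-label">s0</text>
<rect x="110.00" y="38.00" width="18.00" height="18.00" fill="#5a8dff" class="heat-cell" data-row="s1" data-col="s0" data-value="-0.739852"/>
<rect x="128.00" y="38.00" width="18.00" height="18.00" fill="#ff2121" class="heat-cell" data-row="s1" data-col="s1" data-value="1"/>
<rect x="146.00" y="38.00" width="18.00" height="18.00" fill="#a6c2ff" class="heat-cell" data-row="s1" data-col="s3" data-value="-0.39759"/>
<rect x="164.00" y="38.00" width="18.00" height="18.00" fill="#fffefe" class="heat-cell" data-row="s1" data-col="s2" data-value="0.00034101"/>
<text x="186.00" y="50.60" font-size="10" class="row-label">s1</text>
<rect x="110.00" y="56.00" width="18.00" height="18.00" fill="#ffa7a7" class="heat-cell" data-row="s3" data-col="s0" data-value="0.395652"/>
<rect x="128.00" y="56.00" width="18.00" height="18.00" fill="#a6c2ff" class="heat-cell" data-row="s3" data-col="s1" data-value="-0.39759"/>
<rect x="146.00" y="56.00" width="18.00" height="18.00" fill="#ff2121" class="heat-cell" data-row="s3" data-col="s3" data-value="1"/>
<rect x="164.00" y="56.00" width="18.00" height="18.00" fill="#ffeaea" class="heat-cell" data-row="s3" data-col="s2" data-value="0.093519"/>
<text x="186.00" y="68.60" font-size="10" class="row-label">s3</text>
<rect x="110.00" y="74.00" width="18.00" height="18.00" fill="#fff3f3" class="heat-cell" data-row="s2" data-col="s0" data-value="0.0521804"/>
<rect x="128.00" y="74.00" width="18.00" height="18.00" fill="#fffefe" class="heat-cell" data-row="s2" data-col="s1" data-value="0.00034101"/>
<rect x="146.00" y="74.00" width="18.00" height="18.00" fill="#ffeaea" class="heat-cell" data-row="s2" data-col="s3" data-value="0.093519"/>
<rect x="164.00" y="74.00" width="18.00" height="18.00" fill="#ff2121" class="heat-cell" data-row="s2" data-col="s2" data-value="1"/>
<text x="186.00" y="86.60" font-size="10" class="row-label">s2</text>
<line x1="110.00" y1="29.00" x2="86.48" y2="29.00" stroke="#333333" class="dendro"/>
<line x1="110.00" y1="47.00" x2="86.48" y2="47.00" stroke="#333333" class="dendro"/>
<line x1="86.48" y1="29.00" x2="86.48" y2="47.00" stroke="#333333" class="dendro"/>
<line x1="86.48" y1="38.00" x2="55.45" y2="38.00" stroke="#333333" class="dendro"/>
<line x1="110.00" y1="65.00" x2="55.45" y2="65.00" stroke="#333333" class="dendro"/>
<line x1="55.45" y1="38.00" x2="55.45" y2="65.00" stroke="#333333" class="dendro"/>
<line x1="55.45" y1="51.50" x2="24.00" y2="51.50" stroke="#333333" class="dendro"/>
<line x1="110.00" y1="83.00" x2="24.00" y2="83.00" stroke="#333333" class="dendro"/>
<line x1="24.00" y1="51.50" x2="24.00" y2="83.00" stroke="#333333" class="dendro"/>
<rect x="110.00" y="116.00" width="1.80" height="12.00" fill="#2669ff" class="scale-cell"/>
<rect x="111.80" y="116.00" width="1.80" height="12.00" fill="#3171ff" class="scale-cell"/>
<rect x="113.60" y="116.00" width="1.80" height="12.00" fill="#3c79ff" class="scale-cell"/>
<rect x="115.40" y="116.00" width="1.80" height="12.00" fill="#4780ff" class="scale-cell"/>
<rect x="117.20" y="116.00" width="1.80" height="12.00" fill="#5288ff" class="scale-cell"/>
<rect x="119.00" y="116.00" width="1.80" height="12.00" fill="#5e90ff" class="scale-cell"/>
<rect x="120.80" y="116.00" width="1.80" height="12.00" fill="#6997ff" class="scale-cell"/>
<rect x="122.60" y="116.00" width="1.80" height="12.00" fill="#749fff" class="scale-cell"/>
<rect x="124.40" y="116.00" width="1.80" height="12.00" fill="#7fa7ff" class="scale-cell"/>
<rect x="126.20" y="116.00" width="1.80" height="12.00" fill="#8aaeff" class="scale-cell"/>
<rect x="128.00" y="116.00" width="1.80" height="12.00" fill="#95b6ff" class="scale-cell"/>
<rect x="129.80" y="116.00" width="1.80" height="12.00" fill="#a0bdff" class="scale-cell"/>
<rect x="131.60" y="116.00" width="1.80" height="12.00" fill="#abc5ff" class="scale-cell"/>
<rect x="133.40" y="116.00" width="1.80" height="12.00" fill="#b6cdff" class="scale-cell"/>
<rect x="135.20" y="116.00" width="1.80" height="12.00" fill="#c1d4ff" class="scale-cell"/>
<rect x="137.00" y="116.00" width="1.80" height="12.00" fill="#cddcff" class="scale-cell"/>
<rect x="138.80" y="116.00" width="1.80" height="12.00" fill="#d8e4ff" class="scale-cell"/>
<rect x="140.60" y="116.00" width="1.80" height="12.00" fill="#e3ebff" class="scale-cell"/>
<rect x="142.40" y="116.00" width="1.80" height="12.00" fill="#eef3ff" class="scale-cell"/>
<rect x="144.20" y="116.00" width="1.80" height="12.00" fill="#f9fbff" class="scale-cell"/>
<rect x="146.00" y="116.00" width="1.80" height="12.00" fill="#fff9f9" class="scale-cell"/>
<rect x="147.80" y="116.00" width="1.80" height="12.00" fill="#ffeeee" class="scale-cell"/>
<rect x="149.60" y="116.00" width="1.80" height="12.00" fill="#ffe3e3" class="scale-cell"/>
<rect x="151.40" y="116.00" width="1.80" height="12.00" fill="#ffd8d8" class="scale-cell"/>
<rect x="153.20" y="116.00" width="1.80" height="12.00" fill="#ffcdcd" class="scale-cell"/>
<rect x="155.00" y="116.00" width="1.80" height="12.00" fill="#ffc1c1" class="scale-cell"/>
<rect x="156.80" y="116.00" width="1.80" height="12.00" fill="#ffb6b6" class="scale-cell"/>
<rect x="158.60" y="116.00" width="1.80" height="12.00" fill="#ffabab" class="scale-cell"/>
<rect x="160.40" y="116.00" width="1.80" height="12.00" fill="#ffa0a0" class="scale-cell"/>
<rect x="162.20" y="116.00" width="1.80" height="12.00" fill="#ff9595" class="scale-cell"/>
<rect x="164.00" y="116.00" width="1.80" height="12.00" fill="#ff8a8a" class="scale-cell"/>
<rect x="165.80" y="116.00" width="1.80" height="12.00" fill="#ff7f7f" class="scale-cell"/>
<rect x="167.60" y="116.00" width="1.80" height="12.00" fill="#ff7474" class="scale-cell"/>
<rect x="169.40" y="116.00" width="1.80" height="12.00" fill="#ff6969" class="scale-cell"/>
<rect x="171.20" y="116.00" width="1.80" height="12.00" fill="#ff5e5e" class="scale-cell"/>
<rect x="173.00" y="116.00" width="1.80" height="12.00" fill="#ff5252" class="scale-cell"/>
<rect x="174.80" y="116.00" width="1.80" height="12.00" fill="#ff4747" class="scale-cell"/>
<rect x="176.60" y="116.00" width="1.80" height="12.00" fill="#ff3c3c" class="scale-cell"/>
<rect x="178.40" y="116.00" width="1.80" height="12.00" fill="#ff3131" class="scale-cell"/>
<rect x="180.20" y="116.00" width="1.80" height="12.00" fill="#ff2626" class="scale-cell"/>
<text x="110.00" y="140.00" font-size="9" class="scale-label">-1</text>
<text x="182.00" y="140.00" font-size="9" text-anchor="end" class="scale-label">1</text>
<text x="146.00" y="140.00" font-size="9" text-anchor="middle" class="scale-title">correlation</text>
</svg>
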