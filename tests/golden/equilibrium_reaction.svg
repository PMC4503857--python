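<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="460" height="180" viewBox="0 0 460 180">
<rect x="0" y="0" width="460" height="180" fill="#ffffff"/>
<line x1="71.69" y1="90.2" x2="70.99" y2="89.8" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="88.31" y1="90.2" x2="89.01" y2="89.8" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<text x="80" y="99.2" font-family="Helvetica" font-size="12" fill="#ff0d0d" text-anchor="middle" class="label">O</text>
<text x="62.68" y="89.2" font-family="Helvetica" font-size="12" fill="#ffffff" text-anchor="middle" class="label">H</text>
<text x="97.32" y="89.2" font-family="Helvetica" font-size="12" fill="#ffffff" text-anchor="middle" class="label">H</text>
<line x1="379.6" y1="90" x2="380.4" y2="90" stroke="#000000" stroke-width="1" stroke-linecap="round" stroke-dasharray="4 4" class="bond"/>
<text x="370" y="94.2" font-family="Helvetica" font-size="12" fill="#ab5cf2" text-anchor="middle" class="label">Na</text>
<text x="379" y="85.8" font-family="Helvetica" font-size="8.4" fill="#ab5cf2" text-anchor="middle" baseline-shift="super" class="charge">+</text>
<text x="390" y="94.2" font-family="Helvetica" font-size="12" fill="#1ff01f" text-anchor="middle" class="label">Cl</text>
<text x="399" y="85.8" font-family="Helvetica" font-size="8.4" fill="#1ff01f" text-anchor="middle" baseline-shift="super" class="charge">−</text>
<line x1="180" y1="92.94" x2="280" y2="92.94" stroke="#000000" stroke-width="1" stroke-linecap="round" class="arrow"/>
<line x1="280" y1="92.94" x2="271.6" y2="97.14" stroke="#000000" stroke-width="1" stroke-linecap="round" class="harpoon"/>
<line x1="280" y1="87.06" x2="180" y2="87.06" stroke="#000000" stroke-width="1" stroke-linecap="round" class="arrow"/>
<line x1="180" y1="87.06" x2="188.4" y2="82.86" stroke="#000000" stroke-width="1" stroke-linecap="round" class="harpoon"/>
<text x="230" y="79.8" font-family="Helvetica" font-size="12" fill="#000000" text-anchor="middle" class="arrowtext">Δ</text>
</svg>
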