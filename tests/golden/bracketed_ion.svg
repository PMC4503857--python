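<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="220" height="220" viewBox="0 0 220 220">
<rect x="0" y="0" width="220" height="220" fill="#ffffff"/>
<line x1="119.6" y1="110" x2="120.4" y2="110" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="100.4" y1="110" x2="99.6" y2="110" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="108" y1="119.6" x2="108" y2="120.4" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="112" y1="119.6" x2="112" y2="120.4" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="112" y1="100.4" x2="112" y2="99.6" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="108" y1="100.4" x2="108" y2="99.6" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<text x="110" y="114.2" font-family="Helvetica" font-size="12" fill="#ffff30" text-anchor="middle" class="label">S</text>
<text x="130" y="114.2" font-family="Helvetica" font-size="12" fill="#ff0d0d" text-anchor="middle" class="label">O</text>
<text x="139" y="105.8" font-family="Helvetica" font-size="8.4" fill="#ff0d0d" text-anchor="middle" baseline-shift="super" class="charge">−</text>
<text x="90" y="114.2" font-family="Helvetica" font-size="12" fill="#ff0d0d" text-anchor="middle" class="label">O</text>
<text x="99" y="105.8" font-family="Helvetica" font-size="8.4" fill="#ff0d0d" text-anchor="middle" baseline-shift="super" class="charge">−</text>
<text x="110" y="134.2" font-family="Helvetica" font-size="12" fill="#ff0d0d" text-anchor="middle" class="label">O</text>
<text x="110" y="94.2" font-family="Helvetica" font-size="12" fill="#ff0d0d" text-anchor="middle" class="label">O</text>
<polyline points="88.8,88.2 84,88.2 84,140.2 88.8,140.2" fill="none" stroke="#000000" stroke-width="1" stroke-linejoin="round" class="bracket"/>
<polyline points="140.2,88.2 145,88.2 145,140.2 140.2,140.2" fill="none" stroke="#000000" stroke-width="1" stroke-linejoin="round" class="bracket"/>
<text x="148" y="91.8" font-family="Helvetica" font-size="9.6" fill="#000000" text-anchor="start" class="bracket-annotation">2−</text>
</svg>
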