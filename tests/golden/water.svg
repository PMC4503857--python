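<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="200" height="200" viewBox="0 0 200 200">
<rect x="0" y="0" width="200" height="200" fill="#ffffff"/>
<line x1="91.69" y1="100.2" x2="90.99" y2="99.8" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="108.31" y1="100.2" x2="109.01" y2="99.8" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<text x="100" y="109.2" font-family="Helvetica" font-size="12" fill="#ff0d0d" text-anchor="middle" class="label">O</text>
<text x="82.68" y="99.2" font-family="Helvetica" font-size="12" fill="#ffffff" text-anchor="middle" class="label">H</text>
<text x="117.32" y="99.2" font-family="Helvetica" font-size="12" fill="#ffffff" text-anchor="middle" class="label">H</text>
</svg>
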