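<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="300" height="300" viewBox="0 0 300 300">
<rect x="0" y="0" width="300" height="300" fill="#ffffff"/>
<line x1="167.32" y1="160" x2="150" y2="170" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="162.72" y1="158.04" x2="150.6" y2="165.04" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="150" y1="170" x2="132.68" y2="160" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="132.68" y1="160" x2="132.68" y2="140" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="136.68" y1="157" x2="136.68" y2="143" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="132.68" y1="140" x2="150" y2="130" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="150" y1="130" x2="167.32" y2="140" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="150.6" y1="134.96" x2="162.72" y2="141.96" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
<line x1="167.32" y1="140" x2="167.32" y2="160" stroke="#000000" stroke-width="1" stroke-linecap="round" class="bond"/>
</svg>
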